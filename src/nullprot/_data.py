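"""Embedded reference tables.

BLOSUM62_BACKGROUND: marginal target frequencies of the BLOSUM62 substitution
matrix (Henikoff & Henikoff 1992, rounded to three decimals as commonly
published); they sum to exactly 1.000 and serve as the "natural occurrence"
composition model for random-sequence databases.

TOP_IDP: the TOP-IDP per-residue disorder propensity scale (Campen et al.
2008), the basis of the built-in surrogate disorder predictor. Positive
values favour disorder (P, E, K, S ...), negative values favour order
(W, F, Y, I, ...).
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_ORDER

# Henikoff & Henikoff (1992) BLOSUM62 marginal target frequencies.
BLOSUM62_BACKGROUND = {
    "A": 0.074,
    "C": 0.025,
    "D": 0.054,
    "E": 0.054,
    "F": 0.047,
    "G": 0.074,
    "H": 0.026,
    "I": 0.068,
    "K": 0.058,
    "L": 0.099,
    "M": 0.025,
    "N": 0.045,
    "P": 0.039,
    "Q": 0.034,
    "R": 0.052,
    "S": 0.057,
    "T": 0.051,
    "V": 0.073,
    "W": 0.013,
    "Y": 0.032,
}

# Campen et al. (2008), Protein Pept. Lett. 15:956: TOP-IDP scale.
TOP_IDP = {
    "A": 0.060,
    "C": 0.020,
    "D": 0.192,
    "E": 0.736,
    "F": -0.697,
    "G": 0.166,
    "H": 0.303,
    "I": -0.486,
    "K": 0.586,
    "L": -0.326,
    "M": -0.397,
    "N": 0.007,
    "P": 0.987,
    "Q": 0.318,
    "R": 0.180,
    "S": 0.341,
    "T": 0.059,
    "V": -0.121,
    "W": -0.884,
    "Y": -0.510,
}


def background_vector() -> np.ndarray:
    """BLOSUM62 background frequencies in :data:`~nullprot.alphabet.AA_ORDER`."""
    return np.array([BLOSUM62_BACKGROUND[aa] for aa in AA_ORDER], dtype=float)


def top_idp_vector() -> np.ndarray:
    """TOP-IDP propensities in :data:`~nullprot.alphabet.AA_ORDER`."""
    return np.array([TOP_IDP[aa] for aa in AA_ORDER], dtype=float)
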