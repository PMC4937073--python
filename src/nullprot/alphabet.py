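"""The 20-letter amino-acid alphabet and residue encoding helpers.

Every module in the package indexes per-residue quantities (composition
vectors, substitution scores, propensity scales) by the fixed alphabetical
order defined here, so a frequency vector's i-th entry always refers to
``AA_ORDER[i]``.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used for all 20-vectors in this package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: residue letter -> index into AA_ORDER
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

N_AA = 20


def validate_residues(residues: str, *, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending position if any
    character falls outside the 20-letter alphabet."""
    for pos, ch in enumerate(residues, start=1):
        if ch not in AA_INDEX:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} in {context}: "
                f"expected one of {AA_ORDER}"
            )


# ASCII byte -> alphabet index (255 = invalid), for vectorized encoding
_LUT = np.full(128, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _LUT[ord(_aa)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as a uint8 array of alphabet indices."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        validate_residues(residues)  # raises with the offending position
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(AA_ORDER[int(c)] for c in codes)
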