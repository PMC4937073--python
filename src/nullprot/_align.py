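"""Global-alignment identity engine.

Sequence identity here is defined on the optimal global (Needleman-Wunsch)
alignment under BLOSUM62 with affine gaps (open 11, extend 1):

    identity = identical aligned columns / alignment length.

Optimal alignments are generally not unique, so among all score-optimal
alignments we take the one with the most identical columns, breaking any
remaining tie by the fewest gap columns. Because that criterion is a
lexicographic maximum over the (orientation-independent) set of optimal
alignments, the resulting identity is symmetric in its two arguments and
fully deterministic.

The whole criterion is computed in a single Gotoh dynamic program by packing
(score, matches, diagonal-steps) into one integer key:

    key = score << SH_S | matches << SH_M | diag

Packed keys add along an alignment path and compare lexicographically, so
the standard max-plus recursion yields the lexicographic optimum directly —
no traceback, no tie-break bookkeeping. int32 keys cover sequences up to 63
residues (6 bits each for matches and diag); longer sequences use int64
keys. The int32 kernel vectorizes over blocks of sequences (~2 us per pair
for 60-mers), which is what makes the 10,000-sequence greedy redundancy
screen (~5e7 pairs) tractable on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .alphabet import AA_ORDER, N_AA

GAP_OPEN = 11
GAP_EXTEND = 1

# int32 packing: score << 12 | matches << 6 | diag  (lengths <= 63)
_SH_S32, _SH_M32 = 12, 6
_MASK32 = 63
_LEN32 = 63
# int64 packing: score << 32 | matches << 16 | diag (lengths <= 65535)
_SH_S64, _SH_M64 = 32, 16
_MASK64 = 65535


def _blosum62_submatrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((N_AA, N_AA), dtype=np.int64)
    for i, x in enumerate(AA_ORDER):
        for j, y in enumerate(AA_ORDER):
            sub[i, j] = int(B[x, y])
    return sub


#: BLOSUM62 scores indexed by AA_ORDER (loaded from Biopython's tables).
SUBSTITUTION = _blosum62_submatrix()


@njit(cache=True)
def _gotoh_keys(c, delta, gaps, out):
    """Packed-key Gotoh recursion.

    c      : (n,) uint8 candidate residue codes (row sequence)
    delta  : (20, m, nb) diagonal-step keys: delta[aa, j, p] is the key
             increment for aligning residue aa against column j of block
             member p (substitution score, +1 match bit, +1 diag step)
    gaps   : (3,) array [gap_open_key, gap_extend_key, NEG sentinel]
    out    : (nb,) final keys, one per block member
    """
    n = c.shape[0]
    m = delta.shape[1]
    nb = delta.shape[2]
    gok = gaps[0]
    gek = gaps[1]
    neg = gaps[2]
    H = np.empty((m + 1, nb), delta.dtype)
    X = np.empty((m + 1, nb), delta.dtype)  # gap in the column sequence
    dH = np.empty(nb, delta.dtype)
    Y = np.empty(nb, delta.dtype)  # gap in the row sequence
    for p in range(nb):
        H[0, p] = 0
        X[0, p] = neg
    for j in range(1, m + 1):
        v = -gok - (j - 1) * gek
        for p in range(nb):
            H[j, p] = v
            X[j, p] = neg
    for i in range(1, n + 1):
        D = delta[c[i - 1]]
        v0 = -gok - (i - 1) * gek
        for p in range(nb):
            dH[p] = H[0, p]
            H[0, p] = v0
            Y[p] = neg
        for j in range(1, m + 1):
            Xj = X[j]
            Hj = H[j]
            Hj1 = H[j - 1]
            Dj = D[j - 1]
            for p in range(nb):
                xs = max(Xj[p] - gek, Hj[p] - gok)
                ys = max(Y[p] - gek, Hj1[p] - gok)
                hs = max(dH[p] + Dj[p], max(xs, ys))
                Y[p] = ys
                dH[p] = Hj[p]
                Hj[p] = hs
                Xj[p] = xs
    for p in range(nb):
        out[p] = H[m, p]


def _delta_block(codes_cols: np.ndarray, sh_s: int, sh_m: int, dtype) -> np.ndarray:
    """Build the (20, m, nb) diagonal-step key tensor for a block whose
    member sequences are given column-major as ``codes_cols`` (m, nb)."""
    eq = (
        codes_cols[None, :, :] == np.arange(N_AA, dtype=np.uint8)[:, None, None]
    ).astype(np.int64)
    delta = (SUBSTITUTION[:, codes_cols] << sh_s) + (eq << sh_m) + 1
    return np.ascontiguousarray(delta.astype(dtype))


def _decode(key: int, sh_s: int, sh_m: int, mask: int) -> tuple[int, int, int]:
    score = int(key) >> sh_s
    matches = (int(key) >> sh_m) & mask
    diag = int(key) & mask
    return score, matches, diag


def alignment_stats(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(score, matches, diag) of the tie-broken optimal global alignment of
    two encoded sequences. ``diag`` counts non-gap alignment columns, so the
    alignment length is ``len(a) + len(b) - diag``."""
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align an empty sequence")
    if max(a.size, b.size) <= _LEN32:
        sh_s, sh_m, mask, dtype = _SH_S32, _SH_M32, _MASK32, np.int32
        neg = -(2**28)
    else:
        sh_s, sh_m, mask, dtype = _SH_S64, _SH_M64, _MASK64, np.int64
        neg = -(2**60)
    delta = _delta_block(b[:, None], sh_s, sh_m, dtype)
    gaps = np.array([GAP_OPEN << sh_s, GAP_EXTEND << sh_s, neg], dtype=dtype)
    out = np.empty(1, dtype=dtype)
    _gotoh_keys(a, delta, gaps, out)
    return _decode(out[0], sh_s, sh_m, mask)


def identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of identical columns in the tie-broken optimal alignment."""
    _, matches, diag = alignment_stats(a, b)
    return matches / (a.size + b.size - diag)


class IdentityScreen:
    """Grow-only store of fixed-length sequences supporting fast queries of
    the maximum identity between a candidate and everything stored.

    Sequences are kept in blocks of ``block_width``; each block carries a
    precomputed diagonal-key tensor so a single kernel call aligns the
    candidate against the whole block.
    """

    def __init__(self, length: int, block_width: int = 64):
        if length < 1:
            raise ValueError("length must be >= 1")
        self.length = length
        self.block_width = block_width
        if length <= _LEN32:
            self._sh_s, self._sh_m, self._mask = _SH_S32, _SH_M32, _MASK32
            self._dtype, neg = np.int32, -(2**28)
        else:
            self._sh_s, self._sh_m, self._mask = _SH_S64, _SH_M64, _MASK64
            self._dtype, neg = np.int64, -(2**60)
        self._gaps = np.array(
            [GAP_OPEN << self._sh_s, GAP_EXTEND << self._sh_s, neg],
            dtype=self._dtype,
        )
        self._blocks: list[np.ndarray] = []  # (20, L, bw) delta tensors
        self._counts: list[int] = []
        self._out = np.empty(block_width, dtype=self._dtype)
        self.n = 0

    def add(self, codes: np.ndarray) -> None:
        if codes.size != self.length:
            raise ValueError(
                f"sequence length {codes.size} != screen length {self.length}"
            )
        if not self._blocks or self._counts[-1] == self.block_width:
            self._blocks.append(
                np.zeros((N_AA, self.length, self.block_width), dtype=self._dtype)
            )
            self._counts.append(0)
        block = self._blocks[-1]
        p = self._counts[-1]
        eq = (codes[None, :] == np.arange(N_AA, dtype=np.uint8)[:, None]).astype(
            np.int64
        )
        block[:, :, p] = (
            (SUBSTITUTION[:, codes] << self._sh_s) + (eq << self._sh_m) + 1
        )
        self._counts[-1] = p + 1
        self.n += 1

    def max_identity(self, codes: np.ndarray, stop_at: float = 2.0) -> float:
        """Maximum identity of ``codes`` to any stored sequence (0.0 when the
        store is empty). Scanning short-circuits once ``stop_at`` is reached,
        so ``max_identity(c, cutoff) >= cutoff`` is an exact collision test."""
        if codes.size != self.length:
            raise ValueError(
                f"sequence length {codes.size} != screen length {self.length}"
            )
        best = 0.0
        two_l = 2 * self.length
        for block, cnt in zip(self._blocks, self._counts):
            _gotoh_keys(codes, block, self._gaps, self._out)
            keys = self._out[:cnt]
            matches = (keys >> self._sh_m) & self._mask
            diag = keys & self._mask
            ident = matches / (two_l - diag)
            m = float(ident.max())
            if m > best:
                best = m
                if best >= stop_at:
                    return best
        return best
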