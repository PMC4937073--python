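"""Per-residue disorder probabilities and their binarization.

Disorder predictors assign each residue a probability of being
intrinsically disordered; a fixed threshold (0.5 by default) turns the
track into ordered (O) / disordered (D) labels. External predictor output
is read from a simple TSV; the built-in surrogate predictor maps a
windowed mean of the TOP-IDP disorder propensity scale through a logistic
function — it reproduces the correct sign behaviour (disorder-promoting
compositions score high) without emulating any trained predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._data import top_idp_vector
from .alphabet import AA_ORDER
from .seqgen import ProteinSequence

DEFAULT_THRESHOLD = 0.5

ORDERED = "O"
DISORDERED = "D"


@dataclass(frozen=True)
class DisorderScale:
    """Propensity scale + smoothing window + logistic calibration for the
    surrogate predictor.

    The default propensities are the TOP-IDP scale. The logistic midpoint
    sits halfway between the glutamate (disorder-promoting) and isoleucine
    (order-promoting) propensities and the slope is calibrated so that
    poly-E scores 0.90 and poly-I scores 0.10.
    """

    propensities: tuple[float, ...] = tuple(top_idp_vector())
    window: int = 21
    midpoint: float = 0.125
    slope: float = 3.6

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if len(self.propensities) != 20:
            raise ValueError("propensities must have 20 entries (AA_ORDER)")

    def propensity_of(self, residue: str) -> float:
        return self.propensities[AA_ORDER.index(residue)]


DEFAULT_SCALE = DisorderScale()


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue disorder probabilities for one sequence."""

    seq_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"empty score track for {self.seq_id!r}")
        for pos, s in enumerate(self.scores, start=1):
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"score {s!r} at position {pos} of {self.seq_id!r} "
                    "outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


@dataclass(frozen=True)
class RegionLabeling:
    """O/D labels for one sequence, produced at a stated threshold."""

    seq_id: str
    labels: str
    threshold: float

    def __post_init__(self) -> None:
        bad = set(self.labels) - {ORDERED, DISORDERED}
        if bad:
            raise ValueError(f"invalid labels {sorted(bad)} for {self.seq_id!r}")

    def __len__(self) -> int:
        return len(self.labels)


def surrogate_disorder_scores(
    seq: ProteinSequence, scale: DisorderScale = DEFAULT_SCALE
) -> ScoreTrack:
    """Windowed-propensity logistic disorder scores.

    Each position takes the mean scale value over a centered window
    (truncated at the termini — no padding), mapped through
    ``1 / (1 + exp(-slope * (mean - midpoint)))``.
    """
    prop = np.asarray(scale.propensities, dtype=float)[seq.codes]
    h = scale.window // 2
    n = prop.size
    csum = np.concatenate(([0.0], np.cumsum(prop)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    wmean = (csum[hi] - csum[lo]) / (hi - lo)
    scores = 1.0 / (1.0 + np.exp(-scale.slope * (wmean - scale.midpoint)))
    return ScoreTrack(seq_id=seq.id, scores=tuple(map(float, np.clip(scores, 0.0, 1.0))))


def binarize(track: ScoreTrack, threshold: float = DEFAULT_THRESHOLD) -> RegionLabeling:
    """Label D where score >= threshold, else O (ties count as disordered)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    labels = "".join(
        DISORDERED if s >= threshold else ORDERED for s in track.scores
    )
    return RegionLabeling(seq_id=track.seq_id, labels=labels, threshold=threshold)


# ---------------------------------------------------------------------------
# Score-track TSV I/O (columns: seq_id, pos, res, score; pos is 1-based)


def write_score_tracks(
    tracks: Iterable[ScoreTrack], path, sequences: dict[str, str] | None = None
) -> None:
    """Write tracks as TSV. Scores are serialized with ``repr`` so a
    read/write round trip is exact. When ``sequences`` maps seq_id to
    residues, the residue column is filled in; otherwise it holds ``X``."""
    with open(path, "w") as fh:
        fh.write("seq_id\tpos\tres\tscore\n")
        for t in tracks:
            res = sequences.get(t.seq_id) if sequences else None
            for i, s in enumerate(t.scores, start=1):
                r = res[i - 1] if res else "X"
                fh.write(f"{t.seq_id}\t{i}\t{r}\t{float(s)!r}\n")


def read_score_tracks(path, sequences: dict[str, str] | None = None) -> list[ScoreTrack]:
    """Parse a score-track TSV into one track per seq_id.

    Positions must be contiguous from 1 within each id; scores must lie in
    [0, 1]; when ``sequences`` is given, the residue column is checked
    against it. Violations raise with the offending file:line.
    """
    path = Path(path)
    per_id: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.split()[:2] != ["seq_id", "pos"]:
            raise ValueError(f"{path}:1: expected header 'seq_id\\tpos\\tres\\tscore'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            seq_id, pos_s, res, score_s = parts
            pos = int(pos_s)
            score = float(score_s)
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: score {score_s} outside [0, 1]"
                )
            if seq_id not in per_id:
                per_id[seq_id] = []
                order.append(seq_id)
            expected = len(per_id[seq_id]) + 1
            if pos != expected:
                raise ValueError(
                    f"{path}:{lineno}: position {pos} for {seq_id!r} not "
                    f"contiguous (expected {expected})"
                )
            if sequences is not None and seq_id in sequences:
                want = sequences[seq_id][pos - 1]
                if res != "X" and res != want:
                    raise ValueError(
                        f"{path}:{lineno}: residue {res!r} does not match "
                        f"{want!r} in sequence {seq_id!r}"
                    )
            per_id[seq_id].append(score)
    return [ScoreTrack(seq_id=i, scores=tuple(per_id[i])) for i in order]
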