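"""Amino-acid composition profiles and the relative-preference statistic.

The preference of residue type i for a region class is measured relative
to the whole database:

    dP_i = (P_i^region - P_i^all) / P_i^all

where P_i^region is the frequency of type i pooled over all residues of
that class (ordered or disordered) and P_i^all its frequency over every
residue of the database. dP_i >= -1 always, with equality iff the type is
absent from the region class, and the P_all-weighted sum of dP is zero by
construction. Bias vectors from different sources (predicted vs annotated
regions, one database vs another) are compared by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .alphabet import AA_INDEX, AA_ORDER, N_AA
from .scoring import DISORDERED, ORDERED, RegionLabeling
from .seqgen import SequenceDataset


@dataclass(frozen=True)
class CompositionProfile:
    """20 residue-type frequencies plus the residue count they summarize."""

    frequencies: tuple[float, ...]
    n_residues: int

    def __post_init__(self) -> None:
        if len(self.frequencies) != N_AA:
            raise ValueError("expected 20 frequencies")
        if self.n_residues > 0:
            total = float(sum(self.frequencies))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total!r}, not 1")

    @property
    def empty(self) -> bool:
        return self.n_residues == 0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


@dataclass(frozen=True)
class BiasVector:
    """The 20-dimensional dP preference vector for one region class."""

    values: tuple[float, ...]
    region_class: str  # ORDERED or DISORDERED

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class Annotation:
    """One annotated region, 1-based inclusive coordinates."""

    seq_id: str
    start: int
    end: int
    label: str  # "ordered" or "disordered"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad coordinates {self.start}-{self.end} on {self.seq_id!r}"
            )
        if self.label not in ("ordered", "disordered"):
            raise ValueError(f"bad region label {self.label!r} on {self.seq_id!r}")


class AnnotationSet:
    """Region annotations grouped by sequence, validated for overlap."""

    def __init__(self, records: Iterable[Annotation]):
        self.records = list(records)
        by_seq: dict[str, list[Annotation]] = {}
        for r in self.records:
            by_seq.setdefault(r.seq_id, []).append(r)
        for seq_id, recs in by_seq.items():
            recs_sorted = sorted(recs, key=lambda r: r.start)
            for a, b in zip(recs_sorted, recs_sorted[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping regions {a.start}-{a.end} and "
                        f"{b.start}-{b.end} on {seq_id!r}"
                    )
        self.by_seq = by_seq

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def composition_of(residues: str) -> CompositionProfile:
    """Frequency of each residue type in a pooled residue multiset."""
    counts = np.zeros(N_AA)
    for ch in residues:
        try:
            counts[AA_INDEX[ch]] += 1
        except KeyError:
            raise ValueError(f"invalid residue {ch!r}") from None
    n = int(counts.sum())
    freqs = counts / n if n else counts
    return CompositionProfile(frequencies=tuple(map(float, freqs)), n_residues=n)


def bias(
    region_profile: CompositionProfile,
    all_profile: CompositionProfile,
    region_class: str = DISORDERED,
) -> BiasVector:
    """dP_i = (P_i^region - P_i^all) / P_i^all, elementwise."""
    if region_profile.empty:
        raise ValueError("region profile is empty (no residues tallied)")
    p_all = all_profile.as_array()
    zero = np.where(p_all == 0)[0]
    if zero.size:
        raise ValueError(
            f"P_all is zero for residue type {AA_ORDER[zero[0]]!r}; "
            "bias undefined"
        )
    dp = (region_profile.as_array() - p_all) / p_all
    return BiasVector(values=tuple(map(float, dp)), region_class=region_class)


def pearson(x: BiasVector | np.ndarray, y: BiasVector | np.ndarray) -> float:
    """Product-moment correlation between two 20-vectors."""
    xv = x.as_array() if isinstance(x, BiasVector) else np.asarray(x, float)
    yv = y.as_array() if isinstance(y, BiasVector) else np.asarray(y, float)
    if xv.size != yv.size:
        raise ValueError("vectors must have equal length")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance vector; correlation undefined")
    return float(stats.pearsonr(xv, yv).statistic)


def regions_to_residues(
    annotations: AnnotationSet, sequences: SequenceDataset | Mapping[str, str], label: str
) -> str:
    """Concatenated residues of every annotated region with ``label``."""
    if isinstance(sequences, SequenceDataset):
        seq_map = {s.id: s.residues for s in sequences}
    else:
        seq_map = dict(sequences)
    out: list[str] = []
    for r in annotations:
        if r.label != label:
            continue
        if r.seq_id not in seq_map:
            raise ValueError(f"annotation references unknown sequence {r.seq_id!r}")
        seq = seq_map[r.seq_id]
        if r.end > len(seq):
            raise ValueError(
                f"region {r.start}-{r.end} on {r.seq_id!r} exceeds sequence "
                f"length {len(seq)}"
            )
        out.append(seq[r.start - 1 : r.end])
    return "".join(out)


def labeled_residues(
    labelings: Iterable[RegionLabeling],
    sequences: SequenceDataset | Mapping[str, str],
    label: str,
) -> str:
    """Concatenated residues whose per-residue label equals ``label`` —
    the predicted-region analogue of :func:`regions_to_residues`."""
    if label not in (ORDERED, DISORDERED):
        raise ValueError(f"label must be {ORDERED!r} or {DISORDERED!r}")
    if isinstance(sequences, SequenceDataset):
        seq_map = {s.id: s.residues for s in sequences}
    else:
        seq_map = dict(sequences)
    out: list[str] = []
    for lab in labelings:
        seq = seq_map[lab.seq_id]
        if len(seq) != len(lab.labels):
            raise ValueError(
                f"labeling length {len(lab.labels)} != sequence length "
                f"{len(seq)} for {lab.seq_id!r}"
            )
        out.append("".join(c for c, l in zip(seq, lab.labels) if l == label))
    return "".join(out)


# ---------------------------------------------------------------------------
# TSV I/O


def read_annotations(path) -> AnnotationSet:
    """Annotation TSV: seq_id, start, end, label (1-based inclusive)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["seq_id", "start", "end", "label"]:
            raise ValueError(f"{path}:1: expected header seq_id\\tstart\\tend\\tlabel")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            try:
                records.append(
                    Annotation(parts[0], int(parts[1]), int(parts[2]), parts[3])
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return AnnotationSet(records)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlabel\n")
        for r in annotations:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label}\n")


def write_bias_table(
    ordered_bias: BiasVector | None, disordered_bias: BiasVector | None, path
) -> None:
    """Bias-vector TSV: residue, dP_ordered, dP_disordered."""
    with open(path, "w") as fh:
        fh.write("residue\tdP_ordered\tdP_disordered\n")
        for i, aa in enumerate(AA_ORDER):
            o = repr(ordered_bias.values[i]) if ordered_bias else "-"
            d = repr(disordered_bias.values[i]) if disordered_bias else "-"
            fh.write(f"{aa}\t{o}\t{d}\n")
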