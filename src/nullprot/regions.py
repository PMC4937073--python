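"""Run-length statistics of ordered/disordered labelings.

Per sequence: the number of disordered residues and the longest contiguous
disordered (D) and structured (O) runs. Per dataset: integer histograms of
those statistics (reported in log2 counts, zero bins suppressed) and
mean +/- SD summaries over a random equal partition into k subsets — the
presentation used to compare natural and random databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scoring import DISORDERED, ORDERED, RegionLabeling


@dataclass(frozen=True)
class RegionSummary:
    seq_id: str
    length: int
    n_disordered: int
    longest_D: int
    longest_O: int
    longest_D_span: tuple[int, int] | None  # 1-based inclusive, None if no run
    longest_O_span: tuple[int, int] | None

    @property
    def fully_disordered(self) -> bool:
        return self.longest_D == self.length

    @property
    def nearly_fully_structured(self) -> bool:
        """At most 5 disordered residues."""
        return self.n_disordered <= 5

    @property
    def n_structured(self) -> int:
        return self.length - self.n_disordered


@dataclass(frozen=True)
class LengthHistogram:
    """Counts over integer bins 0..max_len with log2 for nonzero bins."""

    statistic: str
    counts: tuple[int, ...]  # index = bin value

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def log2_counts(self) -> dict[int, float]:
        return {
            b: float(np.log2(c)) for b, c in enumerate(self.counts) if c > 0
        }


@dataclass(frozen=True)
class SubsetSummary:
    """Per-bin mean and SD of histogram counts across k random subsets."""

    statistic: str
    k: int
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    seed: int | None = None

    def scaled_log2_mean(self) -> dict[int, float]:
        """log2(mean * k) for nonzero bins — the plotted quantity when a
        dataset is split into k subsets but shown on the full-dataset
        scale ("times k in log2")."""
        return {
            b: float(np.log2(m * self.k))
            for b, m in enumerate(self.mean)
            if m > 0
        }


def _longest_run(labels: str, state: str) -> tuple[int, tuple[int, int] | None]:
    best = 0
    span = None
    run = 0
    for i, ch in enumerate(labels):
        if ch == state:
            run += 1
            if run > best:  # strict: first occurrence wins ties
                best = run
                span = (i - run + 2, i + 1)  # 1-based inclusive
        else:
            run = 0
    return best, span


def summarize_regions(labeling: RegionLabeling) -> RegionSummary:
    """Disordered-residue count and longest O/D runs of one labeling."""
    labels = labeling.labels
    if not labels:
        raise ValueError(f"empty labeling for {labeling.seq_id!r}")
    longest_d, span_d = _longest_run(labels, DISORDERED)
    longest_o, span_o = _longest_run(labels, ORDERED)
    return RegionSummary(
        seq_id=labeling.seq_id,
        length=len(labels),
        n_disordered=labels.count(DISORDERED),
        longest_D=longest_d,
        longest_O=longest_o,
        longest_D_span=span_d,
        longest_O_span=span_o,
    )


def _histogram(values: Iterable[int], max_len: int, statistic: str) -> LengthHistogram:
    counts = [0] * (max_len + 1)
    for v in values:
        if v > max_len:
            raise ValueError(f"{statistic} value {v} exceeds max_len {max_len}")
        counts[v] += 1
    return LengthHistogram(statistic=statistic, counts=tuple(counts))


def disorder_count_histogram(
    summaries: Sequence[RegionSummary], max_len: int
) -> LengthHistogram:
    """Histogram of the number of disordered residues per sequence."""
    return _histogram(
        (s.n_disordered for s in summaries), max_len, "n_disordered"
    )


def longest_region_histogram(
    summaries: Sequence[RegionSummary], state: str, max_len: int
) -> LengthHistogram:
    """Histogram of the longest contiguous run of ``state`` per sequence."""
    if state == DISORDERED:
        values = (s.longest_D for s in summaries)
    elif state == ORDERED:
        values = (s.longest_O for s in summaries)
    else:
        raise ValueError(f"state must be {ORDERED!r} or {DISORDERED!r}")
    return _histogram(values, max_len, f"longest_{state}")


def random_partition(n: int, k: int, seed: int | None) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k equal disjoint subsets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n % k != 0:
        raise ValueError(f"dataset size {n} not divisible by k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    size = n // k
    return [np.sort(perm[i * size : (i + 1) * size]) for i in range(k)]


def subset_mean_sd(
    summaries: Sequence[RegionSummary],
    k: int,
    statistic: str,
    seed: int | None,
    *,
    max_len: int | None = None,
) -> SubsetSummary:
    """Split the dataset into k random equal subsets, histogram ``statistic``
    within each, and report the per-bin mean and SD across subsets.

    ``statistic`` selects the binned quantity: "n_disordered",
    "longest_D" or "longest_O".
    """
    getters = {
        "n_disordered": lambda s: s.n_disordered,
        "longest_D": lambda s: s.longest_D,
        "longest_O": lambda s: s.longest_O,
    }
    if statistic not in getters:
        raise ValueError(f"unknown statistic {statistic!r}")
    get = getters[statistic]
    if max_len is None:
        max_len = max((s.length for s in summaries), default=0)
    parts = random_partition(len(summaries), k, seed)
    table = np.zeros((k, max_len + 1))
    for row, idx in enumerate(parts):
        for i in idx:
            table[row, get(summaries[i])] += 1
    return SubsetSummary(
        statistic=statistic,
        k=k,
        mean=tuple(map(float, table.mean(axis=0))),
        sd=tuple(map(float, table.std(axis=0, ddof=0))),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# TSV output


def write_region_summaries(summaries: Iterable[RegionSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tlength\tn_disordered\tlongest_D\tlongest_O\t"
            "longest_D_span\tlongest_O_span\n"
        )
        for s in summaries:
            sd = "-" if s.longest_D_span is None else "%d-%d" % s.longest_D_span
            so = "-" if s.longest_O_span is None else "%d-%d" % s.longest_O_span
            fh.write(
                f"{s.seq_id}\t{s.length}\t{s.n_disordered}\t{s.longest_D}\t"
                f"{s.longest_O}\t{sd}\t{so}\n"
            )


def write_histogram(hist: LengthHistogram, path) -> None:
    log2 = hist.log2_counts()
    with open(path, "w") as fh:
        fh.write("bin\tcount\tlog2_count\n")
        for b, c in enumerate(hist.counts):
            l2 = f"{log2[b]!r}" if b in log2 else "-"
            fh.write(f"{b}\t{c}\t{l2}\n")
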