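"""Secondary-structure content and segment-length statistics.

Eight-state DSSP-style annotations are merged to three states (H, G, I ->
helix H; B, E -> sheet E; T, S and coil -> C; both '-' and the 'D' coil
token are accepted). Helix/sheet content is computed per protein within a
region class (ordered or disordered residues), segments are maximal H or E
runs with runs crossing an order/disorder boundary split at the boundary,
and databases are compared with Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scoring import DISORDERED, ORDERED, RegionLabeling

SS8_ALPHABET = set("HGIBETSD-")
SS3_ALPHABET = set("HEC")

_SS8_TO_SS3 = {
    "H": "H",
    "G": "H",
    "I": "H",
    "B": "E",
    "E": "E",
    "T": "C",
    "S": "C",
    "D": "C",
    "-": "C",
}


@dataclass(frozen=True)
class SSString:
    """Per-residue secondary-structure states for one sequence."""

    seq_id: str
    states: str

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Segment:
    """A maximal helix or sheet run within one region class."""

    seq_id: str
    state: str  # H or E
    start: int  # 1-based
    length: int
    region_class: str  # ORDERED or DISORDERED


@dataclass(frozen=True)
class ContentSummary:
    """Per-protein helix/sheet fractions within one region class."""

    seq_id: str
    region_class: str
    n_residues: int
    helix_fraction: float
    sheet_fraction: float


def merge_8_to_3(ss8: SSString) -> SSString:
    """Elementwise 8-state to 3-state reduction."""
    out = []
    for pos, ch in enumerate(ss8.states, start=1):
        try:
            out.append(_SS8_TO_SS3[ch])
        except KeyError:
            raise ValueError(
                f"unknown 8-state symbol {ch!r} at position {pos} in "
                f"{ss8.seq_id!r}"
            ) from None
    return SSString(seq_id=ss8.seq_id, states="".join(out))


def _check_pair(ss3: SSString, mask: RegionLabeling) -> None:
    if len(ss3) != len(mask):
        raise ValueError(
            f"secondary-structure length {len(ss3)} != labeling length "
            f"{len(mask)} for {ss3.seq_id!r}"
        )


def extract_segments(
    ss3: SSString, mask: RegionLabeling, region_class: str
) -> list[Segment]:
    """Maximal H/E runs among positions whose mask label equals
    ``region_class``; a run crossing a region boundary is split there."""
    _check_pair(ss3, mask)
    if region_class not in (ORDERED, DISORDERED):
        raise ValueError(f"region_class must be {ORDERED!r} or {DISORDERED!r}")
    segments: list[Segment] = []
    run_state = None
    run_start = 0
    run_len = 0

    def flush():
        nonlocal run_state, run_len
        if run_state in ("H", "E") and run_len > 0:
            segments.append(
                Segment(ss3.seq_id, run_state, run_start, run_len, region_class)
            )
        run_state = None
        run_len = 0

    for i, (st, lab) in enumerate(zip(ss3.states, mask.labels), start=1):
        inside = lab == region_class
        if not inside:
            flush()
            continue
        if st == run_state:
            run_len += 1
        else:
            flush()
            run_state = st
            run_start = i
            run_len = 1
    flush()
    return segments


def content(
    ss3: SSString, mask: RegionLabeling, region_class: str
) -> ContentSummary | None:
    """Helix and sheet fractions over the residues of one region class;
    ``None`` when the protein has no residue in that class."""
    _check_pair(ss3, mask)
    states = [s for s, l in zip(ss3.states, mask.labels) if l == region_class]
    if not states:
        return None
    n = len(states)
    return ContentSummary(
        seq_id=ss3.seq_id,
        region_class=region_class,
        n_residues=n,
        helix_fraction=states.count("H") / n,
        sheet_fraction=states.count("E") / n,
    )


def content_table(
    summaries: Iterable[ContentSummary],
) -> dict[tuple[str, str], tuple[float, float, int]]:
    """Dataset mean +/- SD (per-protein, ddof=0) of helix and sheet
    fractions, keyed by (region_class, 'helix'|'sheet')."""
    per_class: dict[str, list[ContentSummary]] = {}
    for s in summaries:
        per_class.setdefault(s.region_class, []).append(s)
    out: dict[tuple[str, str], tuple[float, float, int]] = {}
    for cls, rows in per_class.items():
        hf = np.array([r.helix_fraction for r in rows])
        sf = np.array([r.sheet_fraction for r in rows])
        out[(cls, "helix")] = (float(hf.mean()), float(hf.std(ddof=0)), len(rows))
        out[(cls, "sheet")] = (float(sf.mean()), float(sf.std(ddof=0)), len(rows))
    return out


def unpaired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns (t, p). Implemented from the Welch formulas; an independent
    statistics library serves as the cross-check in the test suite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("both samples are constant; t undefined")
    sx = vx / x.size
    sy = vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        sx**2 / (x.size - 1) + sy**2 / (y.size - 1)
    )
    from scipy.stats import t as t_dist

    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), p


def segment_length_distribution(
    segments: Iterable[Segment],
    dataset_size: int,
    min_protein_support: int = 5,
) -> list[dict]:
    """Per (state, length): segment count, distinct-protein support, the
    fraction of that state's segments, and log2(fraction * 10000).

    Rows whose protein support is below ``min_protein_support`` are marked
    suppressed (kept in the raw table, hidden from reports) — sizes seen in
    too few proteins are statistically unreliable.
    """
    if min_protein_support < 0:
        raise ValueError("min_protein_support must be >= 0")
    by_key: dict[tuple[str, int], list[Segment]] = {}
    totals: dict[str, int] = {}
    for seg in segments:
        by_key.setdefault((seg.state, seg.length), []).append(seg)
        totals[seg.state] = totals.get(seg.state, 0) + 1
    rows = []
    for (state, length), segs in sorted(by_key.items()):
        support = len({s.seq_id for s in segs})
        fraction = len(segs) / totals[state]
        rows.append(
            {
                "state": state,
                "length": length,
                "count": len(segs),
                "protein_support": support,
                "fraction": fraction,
                "log2_fraction_x10000": float(np.log2(fraction * 10000)),
                "suppressed": support < min_protein_support,
                "dataset_size": dataset_size,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# I/O: FASTA-like secondary-structure records and TSV tables


def read_ss_fasta(path) -> list[SSString]:
    """Read '>id' + state-string records (8- or 3-state alphabets)."""
    out: list[SSString] = []
    seq_id = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if seq_id is not None:
                    out.append(SSString(seq_id, "".join(chunks)))
                seq_id = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if seq_id is not None:
        out.append(SSString(seq_id, "".join(chunks)))
    return out


def write_ss_fasta(records: Iterable[SSString], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.states), width):
                fh.write(rec.states[i : i + width] + "\n")


def write_segment_table(rows: list[dict], path, *, include_suppressed=True) -> None:
    with open(path, "w") as fh:
        fh.write(
            "state\tlength\tcount\tprotein_support\tfraction\t"
            "log2_fraction_x10000\tsuppressed\n"
        )
        for r in rows:
            if r["suppressed"] and not include_suppressed:
                continue
            fh.write(
                f"{r['state']}\t{r['length']}\t{r['count']}\t"
                f"{r['protein_support']}\t{r['fraction']!r}\t"
                f"{r['log2_fraction_x10000']!r}\t{int(r['suppressed'])}\n"
            )


def write_content_table(
    tables: dict[str, dict[tuple[str, str], tuple[float, float, int]]], path
) -> None:
    """Table-1-style layout: one row per database, helix/sheet mean +/- SD
    in structured (O) and disordered (D) regions."""
    with open(path, "w") as fh:
        fh.write(
            "database\thelix_O_mean\thelix_O_sd\tsheet_O_mean\tsheet_O_sd\t"
            "helix_D_mean\thelix_D_sd\tsheet_D_mean\tsheet_D_sd\n"
        )
        for name, tab in tables.items():
            vals = []
            for cls in (ORDERED, DISORDERED):
                for kind in ("helix", "sheet"):
                    if (cls, kind) in tab:
                        m, sd, _ = tab[(cls, kind)]
                        vals += [f"{m:.4f}", f"{sd:.4f}"]
                    else:
                        vals += ["-", "-"]
            fh.write(name + "\t" + "\t".join(vals) + "\n")
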