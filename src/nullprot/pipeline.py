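"""End-to-end comparison of sequence databases.

Orchestrates scoring, binarization, region statistics, composition bias
and secondary-structure statistics for several databases (typically a
natural-like arm and the two random null models), writes every table as
TSV plus a JSON metadata record, and audits the report against the
package's conservation invariants. Runs are deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .composition import (
    AnnotationSet,
    BiasVector,
    bias,
    composition_of,
    labeled_residues,
    pearson,
    regions_to_residues,
    write_bias_table,
)
from .regions import (
    LengthHistogram,
    RegionSummary,
    SubsetSummary,
    disorder_count_histogram,
    longest_region_histogram,
    subset_mean_sd,
    summarize_regions,
    write_histogram,
    write_region_summaries,
)
from .scoring import (
    DISORDERED,
    ORDERED,
    ScoreTrack,
    binarize,
    read_score_tracks,
    surrogate_disorder_scores,
)
from .secstruct import (
    SSString,
    Segment,
    content,
    content_table,
    extract_segments,
    merge_8_to_3,
    read_ss_fasta,
    segment_length_distribution,
    unpaired_t_test,
    write_content_table,
    write_segment_table,
)
from .seqgen import SequenceDataset, read_fasta
from .synthetic import SyntheticStudyConfig, make_synthetic_study


@dataclass
class DatasetInputs:
    """File-based inputs for one database."""

    fasta: str
    tracks: str | None = None  # score TSV; None -> surrogate predictor
    ss: str | None = None  # 8- or 3-state FASTA-like records
    annotations: str | None = None


@dataclass
class StudyConfig:
    """Parameters of a comparison run.

    Defaults follow the study conventions: disorder threshold 0.5, 30%
    identity cutoff, 5 random subsets, segment rows shown only with
    support from at least 5 proteins.
    """

    threshold: float = 0.5
    identity_cutoff: float = 0.3
    k_subsets: int = 5
    min_protein_support: int = 5
    seed: int = 0
    synthetic: SyntheticStudyConfig | None = None
    datasets: dict[str, DatasetInputs] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if not (0 < self.identity_cutoff <= 1):
            raise ValueError("identity cutoff must be in (0, 1]")
        if self.k_subsets < 2:
            raise ValueError("k_subsets must be >= 2")


@dataclass
class DatasetReport:
    name: str
    n_sequences: int
    length: int
    summaries: list[RegionSummary]
    n_disordered_hist: LengthHistogram
    longest_D_hist: LengthHistogram
    longest_O_hist: LengthHistogram
    subset_longest_D: SubsetSummary | None
    subset_longest_O: SubsetSummary | None
    n_fully_disordered: int
    n_nearly_fully_structured: int
    n_55plus_structured: int
    all_profile_frequencies: tuple[float, ...]
    bias_ordered: BiasVector | None
    bias_disordered: BiasVector | None
    annotated_bias_ordered: BiasVector | None
    annotated_bias_disordered: BiasVector | None
    content: dict | None
    segments: list[Segment] | None
    segment_rows: list[dict] | None
    class_state_residues: dict | None  # (class, state) -> residue count


@dataclass
class ComparisonReport:
    config: StudyConfig
    datasets: dict[str, DatasetReport]
    pearson_bias: dict[str, float]  # "a|b|class" -> r
    t_tests: dict[str, tuple[float, float]]  # "a|b|class|kind" -> (t, p)
    metadata: dict


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


def _analyze_dataset(
    name: str,
    dataset: SequenceDataset,
    tracks: list[ScoreTrack],
    ss: list[SSString] | None,
    annotations: AnnotationSet | None,
    config: StudyConfig,
) -> DatasetReport:
    seq_map = {s.id: s.residues for s in dataset}
    length = max(len(s) for s in dataset)
    try:
        labelings = [binarize(t, config.threshold) for t in tracks]
    except ValueError as e:
        raise StageError("binarize", f"dataset {name}: {e}") from e
    summaries = [summarize_regions(lab) for lab in labelings]
    nd_hist = disorder_count_histogram(summaries, length)
    ld_hist = longest_region_histogram(summaries, DISORDERED, length)
    lo_hist = longest_region_histogram(summaries, ORDERED, length)
    sub_d = sub_o = None
    if len(summaries) % config.k_subsets == 0 and len(summaries) >= config.k_subsets:
        sub_d = subset_mean_sd(
            summaries, config.k_subsets, "longest_D", config.seed, max_len=length
        )
        sub_o = subset_mean_sd(
            summaries, config.k_subsets, "longest_O", config.seed, max_len=length
        )
    all_profile = composition_of(dataset.all_residues())
    bias_o = bias_d = None
    res_o = labeled_residues(labelings, seq_map, ORDERED)
    res_d = labeled_residues(labelings, seq_map, DISORDERED)
    if res_o:
        bias_o = bias(composition_of(res_o), all_profile, ORDERED)
    if res_d:
        bias_d = bias(composition_of(res_d), all_profile, DISORDERED)
    ann_o = ann_d = None
    if annotations is not None:
        a_o = regions_to_residues(annotations, seq_map, "ordered")
        a_d = regions_to_residues(annotations, seq_map, "disordered")
        if a_o:
            ann_o = bias(composition_of(a_o), all_profile, ORDERED)
        if a_d:
            ann_d = bias(composition_of(a_d), all_profile, DISORDERED)
    cont = segs = seg_rows = class_res = None
    if ss is not None:
        ss3 = [
            s if set(s.states) <= set("HEC") else merge_8_to_3(s) for s in ss
        ]
        lab_map = {l.seq_id: l for l in labelings}
        cont_rows = []
        segs = []
        class_res = {}
        for s in ss3:
            mask = lab_map.get(s.seq_id)
            if mask is None:
                raise StageError("secstruct", f"no labeling for {s.seq_id!r}")
            for cls in (ORDERED, DISORDERED):
                c = content(s, mask, cls)
                if c is not None:
                    cont_rows.append(c)
                segs.extend(extract_segments(s, mask, cls))
                for st in ("H", "E"):
                    key = (cls, st)
                    cnt = sum(
                        1
                        for a, l in zip(s.states, mask.labels)
                        if a == st and l == cls
                    )
                    class_res[key] = class_res.get(key, 0) + cnt
        cont = {"rows": cont_rows, "table": content_table(cont_rows)}
        seg_rows = segment_length_distribution(
            segs, len(dataset), config.min_protein_support
        )
    return DatasetReport(
        name=name,
        n_sequences=len(dataset),
        length=length,
        summaries=summaries,
        n_disordered_hist=nd_hist,
        longest_D_hist=ld_hist,
        longest_O_hist=lo_hist,
        subset_longest_D=sub_d,
        subset_longest_O=sub_o,
        n_fully_disordered=sum(1 for s in summaries if s.fully_disordered),
        n_nearly_fully_structured=sum(
            1 for s in summaries if s.nearly_fully_structured
        ),
        n_55plus_structured=sum(1 for s in summaries if s.n_structured >= 55),
        all_profile_frequencies=all_profile.frequencies,
        bias_ordered=bias_o,
        bias_disordered=bias_d,
        annotated_bias_ordered=ann_o,
        annotated_bias_disordered=ann_d,
        content=cont,
        segments=segs,
        segment_rows=seg_rows,
        class_state_residues=class_res,
    )


def run_comparison(config: StudyConfig, outdir=None) -> ComparisonReport:
    """Execute score -> binarize -> region stats -> composition bias ->
    secondary-structure stats for every configured dataset and assemble
    the comparison report (writing TSV tables + report.json under
    ``outdir`` when given)."""
    inputs: dict[str, tuple] = {}
    if config.synthetic is not None:
        study = make_synthetic_study(config.synthetic)
        for name, ds in study.datasets.items():
            inputs[name] = (
                ds,
                study.tracks[name],
                study.ss8[name],
                study.annotations[name],
            )
    for name, spec in config.datasets.items():
        try:
            ds = read_fasta(spec.fasta, name=name)
        except Exception as e:
            raise StageError("ingest", f"dataset {name}: {e}") from e
        if not len(ds):
            raise StageError("ingest", f"dataset {name} is empty")
        seq_map = {s.id: s.residues for s in ds}
        if spec.tracks:
            tracks = read_score_tracks(spec.tracks, seq_map)
        else:
            tracks = [surrogate_disorder_scores(s) for s in ds]
        ss = read_ss_fasta(spec.ss) if spec.ss else None
        ann = None
        if spec.annotations:
            from .composition import read_annotations

            ann = read_annotations(spec.annotations)
        inputs[name] = (ds, tracks, ss, ann)
    if not inputs:
        raise StageError("ingest", "no datasets configured")

    reports = {
        name: _analyze_dataset(name, *args, config) for name, args in inputs.items()
    }

    pearsons: dict[str, float] = {}
    names = list(reports)
    for cls, attr, ann_attr in (
        (ORDERED, "bias_ordered", "annotated_bias_ordered"),
        (DISORDERED, "bias_disordered", "annotated_bias_disordered"),
    ):
        for i, a in enumerate(names):
            ra = reports[a]
            if getattr(ra, attr) is not None and getattr(ra, ann_attr) is not None:
                pearsons[f"{a}|annotated|{cls}"] = pearson(
                    getattr(ra, attr), getattr(ra, ann_attr)
                )
            for b in names[i + 1 :]:
                rb = reports[b]
                if getattr(ra, attr) is not None and getattr(rb, attr) is not None:
                    pearsons[f"{a}|{b}|{cls}"] = pearson(
                        getattr(ra, attr), getattr(rb, attr)
                    )

    t_tests: dict[str, tuple[float, float]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ca, cb = reports[a].content, reports[b].content
            if ca is None or cb is None:
                continue
            for cls in (ORDERED, DISORDERED):
                for kind in ("helix", "sheet"):
                    xs = [
                        getattr(r, f"{kind}_fraction")
                        for r in ca["rows"]
                        if r.region_class == cls
                    ]
                    ys = [
                        getattr(r, f"{kind}_fraction")
                        for r in cb["rows"]
                        if r.region_class == cls
                    ]
                    if len(xs) >= 2 and len(ys) >= 2:
                        try:
                            t_tests[f"{a}|{b}|{cls}|{kind}"] = unpaired_t_test(xs, ys)
                        except ValueError:
                            pass

    cfg_text = json.dumps(
        {
            "threshold": config.threshold,
            "identity_cutoff": config.identity_cutoff,
            "k_subsets": config.k_subsets,
            "min_protein_support": config.min_protein_support,
            "seed": config.seed,
            "synthetic": config.synthetic is not None,
            "datasets": sorted(config.datasets),
        },
        sort_keys=True,
    )
    metadata = {
        "package_version": __version__,
        "config": json.loads(cfg_text),
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "record_counts": {n: r.n_sequences for n, r in reports.items()},
    }
    report = ComparisonReport(
        config=config, datasets=reports, pearson_bias=pearsons, t_tests=t_tests,
        metadata=metadata,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: ComparisonReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    content_tables = {}
    for name, r in report.datasets.items():
        write_region_summaries(r.summaries, outdir / f"{name}_regions.tsv")
        write_histogram(r.n_disordered_hist, outdir / f"{name}_n_disordered_hist.tsv")
        write_histogram(r.longest_D_hist, outdir / f"{name}_longest_D_hist.tsv")
        write_histogram(r.longest_O_hist, outdir / f"{name}_longest_O_hist.tsv")
        if r.bias_ordered or r.bias_disordered:
            write_bias_table(
                r.bias_ordered, r.bias_disordered, outdir / f"{name}_bias.tsv"
            )
        if r.segment_rows is not None:
            write_segment_table(r.segment_rows, outdir / f"{name}_segments.tsv")
        if r.content is not None:
            content_tables[name] = r.content["table"]
        if r.subset_longest_D is not None:
            with open(outdir / f"{name}_subsets_longest_D.tsv", "w") as fh:
                fh.write("bin\tmean\tsd\tlog2_mean_xk\n")
                scaled = r.subset_longest_D.scaled_log2_mean()
                for b, (m, sd) in enumerate(
                    zip(r.subset_longest_D.mean, r.subset_longest_D.sd)
                ):
                    l2 = repr(scaled[b]) if b in scaled else "-"
                    fh.write(f"{b}\t{m!r}\t{sd!r}\t{l2}\n")
    if content_tables:
        write_content_table(content_tables, outdir / "content_summary.tsv")
    summary = {
        "metadata": report.metadata,
        "headline": {
            name: {
                "n_sequences": r.n_sequences,
                "n_fully_disordered": r.n_fully_disordered,
                "n_nearly_fully_structured": r.n_nearly_fully_structured,
                "n_55plus_structured": r.n_55plus_structured,
            }
            for name, r in report.datasets.items()
        },
        "pearson_bias": report.pearson_bias,
        "t_tests": {
            k: {"t": t, "p": p} for k, (t, p) in report.t_tests.items()
        },
        "violations": validate_report(report),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2) + "\n")


def validate_report(report: ComparisonReport) -> list[str]:
    """Run the conservation and normalization audits; empty list = clean."""
    violations: list[str] = []
    for name, r in report.datasets.items():
        for hist_name in ("n_disordered_hist", "longest_D_hist", "longest_O_hist"):
            hist = getattr(r, hist_name)
            if hist.total != r.n_sequences:
                violations.append(
                    f"{name}.{hist_name}: counts sum to {hist.total}, "
                    f"expected {r.n_sequences}"
                )
        p_all = np.asarray(r.all_profile_frequencies)
        for attr in ("bias_ordered", "bias_disordered"):
            bv = getattr(r, attr)
            if bv is not None:
                w = float(np.dot(p_all, bv.as_array()))
                if abs(w) > 1e-9:
                    violations.append(
                        f"{name}.{attr}: weighted bias sum {w:.3e} != 0"
                    )
        if r.subset_longest_D is not None:
            total = sum(r.subset_longest_D.mean) * r.subset_longest_D.k
            if abs(total - r.n_sequences) > 1e-6:
                violations.append(
                    f"{name}.subset_longest_D: subset means sum to {total}, "
                    f"expected {r.n_sequences}"
                )
        if r.segments is not None and r.class_state_residues is not None:
            seg_sum: dict[tuple[str, str], int] = {}
            for seg in r.segments:
                key = (seg.region_class, seg.state)
                seg_sum[key] = seg_sum.get(key, 0) + seg.length
            for key, expected in r.class_state_residues.items():
                got = seg_sum.get(key, 0)
                if got != expected:
                    violations.append(
                        f"{name}.segments {key}: lengths sum to {got}, "
                        f"expected {expected} residues"
                    )
    return violations
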