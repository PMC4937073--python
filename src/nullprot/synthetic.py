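"""Download-free synthetic study with known ground truth.

Emulates the three-database comparison design (a natural-like set, a
random set at background composition, a random set at uniform composition)
without any external data: every sequence is tiled with planted ordered /
disordered intervals, disordered intervals draw their residues from a
disorder-biased composition (D/E/K/R/S/P/Q enriched, W/C/F/I/Y/V depleted
relative to the arm background, the direction disorder classifiers rely
on), score tracks are the true 0/1 labels plus truncated Gaussian noise,
and secondary-structure strings are emitted per residue from per-class
state probabilities. The recorded truth object lets every downstream
statistic be checked against its planted value.

Arm defaults mirror the comparison qualitatively: the natural-like arm has
many fully disordered sequences and long disordered regions, the
background-composition arm fewer, the uniform-composition arm none
(full-disorder probabilities 0.095 / 0.014 / 0 — the prevalence pattern
observed when natural sequence databases are compared with compositional
null models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import AA_INDEX, N_AA, decode
from .composition import (
    Annotation,
    AnnotationSet,
    BiasVector,
    bias,
    composition_of,
    write_bias_table,
)
from .regions import (
    disorder_count_histogram,
    longest_region_histogram,
    summarize_regions,
    write_histogram,
    write_region_summaries,
)
from .scoring import DISORDERED, ORDERED, RegionLabeling, ScoreTrack
from .secstruct import SSString
from .seqgen import (
    CompositionModel,
    ProteinSequence,
    SequenceDataset,
    load_background_frequencies,
    uniform_frequencies,
)

SS8_STATES = "HGIBETSD"  # D = coil token of the 8-state dialect

#: disordered-region composition = arm background * these multipliers,
#: renormalized (disorder-promoting types up, order-promoting down)
DEFAULT_DISORDER_MULTIPLIERS = {
    "D": 1.8, "E": 1.8, "K": 1.8, "R": 1.8, "S": 1.8, "P": 1.8, "Q": 1.8,
    "W": 0.4, "C": 0.4, "F": 0.4, "I": 0.4, "Y": 0.4, "V": 0.4,
}

#: per-class 8-state emission probabilities (order: HGIBETSD)
DEFAULT_SS_EMISSION = {
    ORDERED: (0.33, 0.03, 0.01, 0.02, 0.25, 0.14, 0.10, 0.12),
    DISORDERED: (0.12, 0.02, 0.00, 0.01, 0.07, 0.22, 0.20, 0.36),
}


@dataclass(frozen=True)
class ArmSpec:
    """One synthetic database arm."""

    name: str
    model_kind: str  # "background" or "uniform"
    p_full_disorder: float
    mean_disorder_len: float
    mean_order_len: float
    p_start_disordered: float | None = None  # default: mean_D/(mean_D+mean_O)

    def __post_init__(self) -> None:
        if not (0 <= self.p_full_disorder <= 1):
            raise ValueError("p_full_disorder must be in [0, 1]")
        if self.mean_disorder_len < 1 or self.mean_order_len < 1:
            raise ValueError("mean region lengths must be >= 1")

    @property
    def start_prob(self) -> float:
        if self.p_start_disordered is not None:
            return self.p_start_disordered
        return self.mean_disorder_len / (self.mean_disorder_len + self.mean_order_len)

    def model(self) -> CompositionModel:
        if self.model_kind == "background":
            return load_background_frequencies()
        if self.model_kind == "uniform":
            return uniform_frequencies()
        raise ValueError(f"unknown model kind {self.model_kind!r}")


DEFAULT_ARMS = (
    ArmSpec("pnat_like", "background", 0.095, 12.0, 20.0),
    ArmSpec("prnd_like", "background", 0.014, 8.0, 22.0),
    ArmSpec("preq_like", "uniform", 0.0, 5.0, 25.0),
)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n: int = 2000
    length: int = 60
    noise_sd: float = 0.1
    seed: int = 0
    arms: tuple[ArmSpec, ...] = DEFAULT_ARMS
    disorder_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISORDER_MULTIPLIERS)
    )
    ss_emission: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SS_EMISSION)
    )

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, probs in self.ss_emission.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"ss emission for {cls!r} does not sum to 1")


@dataclass
class ArmTruth:
    """Planted ground truth for one arm."""

    name: str
    intervals: list[list[tuple[int, int, str]]]  # per sequence, 1-based inclusive
    labels: list[RegionLabeling]  # true O/D labels
    planted_full_disorder: list[bool]
    disorder_frequencies: tuple[float, ...]  # composition D residues drew from
    bias_vector: BiasVector  # realized true disordered-region bias


@dataclass
class SyntheticTruth:
    arms: dict[str, ArmTruth]
    noise_sd: float
    ss_emission: dict[str, tuple[float, ...]]
    seed: int


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    datasets: dict[str, SequenceDataset]
    tracks: dict[str, list[ScoreTrack]]
    ss8: dict[str, list[SSString]]
    annotations: dict[str, AnnotationSet]
    truth: SyntheticTruth


def _disorder_frequencies(
    background: np.ndarray, multipliers: Mapping[str, float]
) -> np.ndarray:
    mult = np.ones(N_AA)
    for aa, m in multipliers.items():
        mult[AA_INDEX[aa]] = m
    biased = background * mult
    return biased / biased.sum()


def _plant_intervals(
    rng: np.random.Generator, length: int, spec: ArmSpec
) -> tuple[list[tuple[int, int, str]], bool]:
    if rng.random() < spec.p_full_disorder:
        return [(1, length, "disordered")], True
    disordered = rng.random() < spec.start_prob
    pos = 1
    intervals: list[tuple[int, int, str]] = []
    while pos <= length:
        mean = spec.mean_disorder_len if disordered else spec.mean_order_len
        if mean > length:
            raise ValueError(
                f"mean region length {mean} exceeds sequence length {length}"
            )
        run = int(rng.geometric(1.0 / mean))
        end = min(pos + run - 1, length)
        intervals.append((pos, end, "disordered" if disordered else "ordered"))
        pos = end + 1
        disordered = not disordered
    return intervals, False


def make_synthetic_study(
    config: SyntheticStudyConfig = SyntheticStudyConfig(),
) -> SyntheticStudy:
    """Generate sequences, truth labels, noisy score tracks, 8-state
    secondary structure and annotations for every arm, reproducibly from
    ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    arm_seeds = root.spawn(len(config.arms))
    ss_order = list(SS8_STATES)
    datasets: dict[str, SequenceDataset] = {}
    tracks: dict[str, list[ScoreTrack]] = {}
    ss8: dict[str, list[SSString]] = {}
    annotations: dict[str, AnnotationSet] = {}
    truths: dict[str, ArmTruth] = {}
    for spec, sseq in zip(config.arms, arm_seeds):
        gen_rng, noise_rng, ss_rng = (np.random.default_rng(s) for s in sseq.spawn(3))
        model = spec.model()
        background = model.as_array()
        dis_freqs = _disorder_frequencies(background, config.disorder_multipliers)
        width = max(5, len(str(config.n - 1)))
        seqs: list[ProteinSequence] = []
        arm_tracks: list[ScoreTrack] = []
        arm_ss: list[SSString] = []
        ann_records: list[Annotation] = []
        all_intervals: list[list[tuple[int, int, str]]] = []
        labelings: list[RegionLabeling] = []
        planted_full: list[bool] = []
        for i in range(config.n):
            seq_id = f"{spec.name}_{i:0{width}d}"
            intervals, is_full = _plant_intervals(gen_rng, config.length, spec)
            codes = np.empty(config.length, dtype=np.uint8)
            label_chars: list[str] = []
            for start, end, lab in intervals:
                m = end - start + 1
                freqs = dis_freqs if lab == "disordered" else background
                codes[start - 1 : end] = gen_rng.choice(N_AA, size=m, p=freqs)
                label_chars.append((DISORDERED if lab == "disordered" else ORDERED) * m)
                ann_records.append(Annotation(seq_id, start, end, lab))
            labels = "".join(label_chars)
            seqs.append(ProteinSequence(seq_id, decode(codes)))
            labelings.append(
                RegionLabeling(seq_id=seq_id, labels=labels, threshold=0.5)
            )
            truth01 = np.array([1.0 if c == DISORDERED else 0.0 for c in labels])
            noise = config.noise_sd * noise_rng.standard_normal(config.length)
            scores = np.clip(truth01 + noise, 0.0, 1.0)
            arm_tracks.append(ScoreTrack(seq_id=seq_id, scores=tuple(map(float, scores))))
            states = []
            for c in labels:
                probs = config.ss_emission[c]
                states.append(ss_order[ss_rng.choice(len(ss_order), p=probs)])
            arm_ss.append(SSString(seq_id=seq_id, states="".join(states)))
            all_intervals.append(intervals)
            planted_full.append(is_full)
        dataset = SequenceDataset(
            name=spec.name, sequences=seqs, model=model, seed=config.seed
        )
        # realized truth bias: disordered-region composition vs whole-arm
        dis_residues = "".join(
            s.residues[start - 1 : end]
            for s, ivs in zip(seqs, all_intervals)
            for start, end, lab in ivs
            if lab == "disordered"
        )
        truth_bias = bias(
            composition_of(dis_residues),
            composition_of(dataset.all_residues()),
            region_class=DISORDERED,
        )
        datasets[spec.name] = dataset
        tracks[spec.name] = arm_tracks
        ss8[spec.name] = arm_ss
        annotations[spec.name] = AnnotationSet(ann_records)
        truths[spec.name] = ArmTruth(
            name=spec.name,
            intervals=all_intervals,
            labels=labelings,
            planted_full_disorder=planted_full,
            disorder_frequencies=tuple(map(float, dis_freqs)),
            bias_vector=truth_bias,
        )
    truth = SyntheticTruth(
        arms=truths,
        noise_sd=config.noise_sd,
        ss_emission={k: tuple(v) for k, v in config.ss_emission.items()},
        seed=config.seed,
    )
    return SyntheticStudy(
        config=config,
        datasets=datasets,
        tracks=tracks,
        ss8=ss8,
        annotations=annotations,
        truth=truth,
    )


def truth_report(truth: SyntheticTruth, outdir=None, *, max_len: int | None = None):
    """Tables of the generator's true statistics, schema-identical to the
    analysis outputs so recovery can be compared field by field.

    Returns {arm: {"summaries", "n_disordered_hist", "longest_D_hist",
    "longest_O_hist", "bias"}} and writes the TSVs when ``outdir`` given.
    """
    report = {}
    for name, arm in truth.arms.items():
        summaries = [summarize_regions(lab) for lab in arm.labels]
        length = max_len if max_len is not None else max(s.length for s in summaries)
        tables = {
            "summaries": summaries,
            "n_disordered_hist": disorder_count_histogram(summaries, length),
            "longest_D_hist": longest_region_histogram(summaries, DISORDERED, length),
            "longest_O_hist": longest_region_histogram(summaries, ORDERED, length),
            "bias": arm.bias_vector,
        }
        report[name] = tables
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_region_summaries(summaries, outdir / f"truth_{name}_regions.tsv")
            write_histogram(
                tables["n_disordered_hist"],
                outdir / f"truth_{name}_n_disordered_hist.tsv",
            )
            write_histogram(
                tables["longest_D_hist"], outdir / f"truth_{name}_longest_D_hist.tsv"
            )
            write_histogram(
                tables["longest_O_hist"], outdir / f"truth_{name}_longest_O_hist.tsv"
            )
            write_bias_table(None, arm.bias_vector, outdir / f"truth_{name}_bias.tsv")
    return report
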