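"""Construction of protein sequence databases.

Three kinds of database are used throughout the package: a natural set
ingested from FASTA, and two random sets drawn i.i.d. per position from a
compositional null model — either the BLOSUM62 background frequencies
("natural occurrence" of residue types) or the uniform model with every
type at 5%. Databases are screened for redundancy with a greedy incremental
clustering at a sequence-identity cutoff (30% by default, mirroring
BLASTClust/CD-HIT usage); random generation regenerates colliding draws so
the screened database still reaches its nominal size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _align
from ._data import background_vector
from .alphabet import N_AA, decode, encode, validate_residues

DEFAULT_IDENTITY_CUTOFF = 0.3
_RETRY_FACTOR = 1000  # max draws per requested sequence during regeneration


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        validate_residues(self.residues, context=f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.residues)


@dataclass(frozen=True)
class CompositionModel:
    """A 20-dimensional residue-frequency model (indexed by AA_ORDER)."""

    kind: str  # "background" or "uniform"
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies) != N_AA:
            raise ValueError(f"expected {N_AA} frequencies, got {len(self.frequencies)}")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("frequencies must be non-negative")
        total = float(sum(self.frequencies))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies must sum to 1 within 1e-9, got {total!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


def load_background_frequencies() -> CompositionModel:
    """The BLOSUM62 background (marginal target) frequencies."""
    return CompositionModel(kind="background", frequencies=tuple(background_vector()))


def uniform_frequencies() -> CompositionModel:
    """The fixed 5%-per-type composition model."""
    return CompositionModel(kind="uniform", frequencies=(0.05,) * N_AA)


@dataclass
class SequenceDataset:
    """A named, ordered collection of unique-id protein sequences."""

    name: str
    sequences: list[ProteinSequence]
    model: CompositionModel | None = None
    seed: int | None = None
    identity_cutoff: float | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r} in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> ProteinSequence:
        return self.sequences[i]

    def all_residues(self) -> str:
        return "".join(s.residues for s in self.sequences)


def _draw_codes(rng: np.random.Generator, freqs: np.ndarray, shape) -> np.ndarray:
    return rng.choice(N_AA, size=shape, p=freqs).astype(np.uint8)


def _seq_id(prefix: str, index: int, width: int) -> str:
    return f"{prefix}{index:0{width}d}"


def generate_random_dataset(
    model: CompositionModel,
    n: int,
    length: int,
    seed: int,
    *,
    name: str = "random",
    id_prefix: str | None = None,
) -> SequenceDataset:
    """Draw ``n`` i.i.d. sequences of ``length`` residues from ``model``.

    Ids are deterministic zero-padded indices; the same (model, n, length,
    seed) always produces byte-identical output.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = model.as_array()
    codes = _draw_codes(rng, freqs, (n, length))
    prefix = id_prefix if id_prefix is not None else f"{name}_"
    width = max(5, len(str(max(n - 1, 0))))
    seqs = [
        ProteinSequence(_seq_id(prefix, i, width), decode(codes[i])) for i in range(n)
    ]
    return SequenceDataset(name=name, sequences=seqs, model=model, seed=seed)


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Sequence identity of the optimal global alignment (see
    :mod:`nullprot._align` for the exact, symmetric convention)."""
    return _align.identity(a.codes, b.codes)


def redundancy_filter(
    dataset: SequenceDataset, cutoff: float = DEFAULT_IDENTITY_CUTOFF
) -> SequenceDataset:
    """Greedy incremental clustering in input order: a sequence is retained
    iff its identity to every previously retained sequence is < ``cutoff``."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    lengths = {len(s) for s in dataset}
    retained: list[ProteinSequence] = []
    if len(lengths) == 1 and dataset.sequences:
        screen = _align.IdentityScreen(lengths.pop())
        for seq in dataset:
            codes = seq.codes
            if screen.n == 0 or screen.max_identity(codes, stop_at=cutoff) < cutoff:
                screen.add(codes)
                retained.append(seq)
    else:
        kept_codes: list[np.ndarray] = []
        for seq in dataset:
            codes = seq.codes
            if all(_align.identity(codes, k) < cutoff for k in kept_codes):
                kept_codes.append(codes)
                retained.append(seq)
    return SequenceDataset(
        name=dataset.name,
        sequences=retained,
        model=dataset.model,
        seed=dataset.seed,
        identity_cutoff=cutoff,
    )


def generate_screened_dataset(
    model: CompositionModel,
    n: int,
    length: int,
    seed: int,
    cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    *,
    name: str = "random",
    id_prefix: str | None = None,
) -> SequenceDataset:
    """Generate a random database of exactly ``n`` mutually non-redundant
    sequences: draws that reach ``cutoff`` identity to an already retained
    sequence are discarded and replaced by fresh draws (capped at
    ``1000 * n`` total draws)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    rng = np.random.default_rng(seed)
    freqs = model.as_array()
    prefix = id_prefix if id_prefix is not None else f"{name}_"
    width = max(5, len(str(max(n - 1, 0))))
    screen = _align.IdentityScreen(length)
    retained: list[ProteinSequence] = []
    draws = 0
    chunk = max(64, min(1024, n)) if n else 0
    while len(retained) < n:
        if draws >= _RETRY_FACTOR * n:
            raise RuntimeError(
                f"redundancy screen exhausted {draws} draws while retaining "
                f"{len(retained)}/{n} sequences at cutoff {cutoff}"
            )
        batch = _draw_codes(rng, freqs, (chunk, length))
        for row in batch:
            draws += 1
            if screen.n and screen.max_identity(row, stop_at=cutoff) >= cutoff:
                continue
            screen.add(row)
            retained.append(
                ProteinSequence(_seq_id(prefix, len(retained), width), decode(row))
            )
            if len(retained) == n:
                break
    return SequenceDataset(
        name=name, sequences=retained, model=model, seed=seed, identity_cutoff=cutoff
    )


# ---------------------------------------------------------------------------
# FASTA + metadata I/O


def write_fasta(dataset: SequenceDataset | Iterable[ProteinSequence], path) -> None:
    """Write sequences as wrapped FASTA with bare ``>id`` header lines."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in iter(dataset)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, *, name: str | None = None) -> SequenceDataset:
    seqs = [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return SequenceDataset(name=name or Path(path).stem, sequences=seqs)


def write_metadata(dataset: SequenceDataset, path) -> None:
    """JSON sidecar recording how a dataset was built."""
    meta = {
        "name": dataset.name,
        "n_sequences": len(dataset),
        "model_kind": dataset.model.kind if dataset.model else None,
        "frequencies": list(dataset.model.frequencies) if dataset.model else None,
        "seed": dataset.seed,
        "identity_cutoff": dataset.identity_cutoff,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
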