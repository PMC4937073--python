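# nullprot

Compositional null models and intrinsic-disorder / secondary-structure
statistics for protein sequences.

## What it is for

How do natural protein sequences differ from random ones? A standard way to
ask this computationally is to compare a database of natural sequences
against random databases drawn from compositional null models — one using
the natural occurrence rates of the 20 amino-acid types (the BLOSUM62
background frequencies) and one fixing every type at 5% — and then to
contrast their predicted intrinsic disorder and secondary structure.
`nullprot` implements that comparison as a reusable, fully testable
pipeline for structural bioinformaticians:

- **Database construction** — random sequence generation under either null
  model, plus a greedy sequence-identity redundancy screen (30% cutoff by
  default) with regeneration, so screened databases reach their nominal
  size (default 10,000 sequences × 60 residues).
- **Disorder scoring** — per-residue disorder probabilities from any
  external predictor (TSV interchange) or from a built-in propensity-based
  surrogate; binarization at a threshold (default 0.5, ties disordered).
- **Region statistics** — per-sequence disordered-residue counts and the
  longest contiguous disordered/structured runs; log2 histograms; mean ± SD
  over k random equal subsets.
- **Composition bias** — ΔP_i = (P_i^region − P_i^all)/P_i^all for
  ordered/disordered regions, predicted or annotated, compared by Pearson
  correlation.
- **Secondary structure** — 8→3 state reduction (H,G,I→H; B,E→E; T,S,coil→C),
  per-protein helix/sheet content by region class, Welch's unpaired t-test
  between databases, and segment-length distributions with a
  protein-support filter.
- **Synthetic study generator** — a three-arm study with planted regions,
  known composition bias, noisy score tracks and emitted secondary
  structure, so every downstream statistic can be verified against ground
  truth without downloading anything.

Sequence identity is defined on the optimal global alignment (BLOSUM62,
gap open 11 / extend 1) as identical columns over alignment length, with a
deterministic, symmetric tie-break (most identities, then fewest gaps,
among score-optimal alignments); a numba-vectorized kernel makes the
~5×10⁷ pair comparisons of a full redundancy screen run in minutes.

## Worked example

Run the default synthetic comparison (2000 sequences per arm, noise SD 0.1)
from Python:

```python
from nullprot import (StudyConfig, SyntheticStudyConfig,
                      run_comparison, validate_report)

cfg = StudyConfig(seed=7, synthetic=SyntheticStudyConfig(n=2000, seed=7))
rep = run_comparison(cfg, outdir="report/")
print(validate_report(rep))           # -> []
for name, r in rep.datasets.items():
    print(name, r.n_fully_disordered, r.n_55plus_structured)
```

prints

```
[]
pnat_like 183 182
prnd_like 31 366
preq_like 0 678
```

i.e. the natural-like arm has far more fully disordered sequences (183 vs
31 vs 0) — the planted long-disorder excess of natural sequences — while
the random arms have *more* sequences with ≥55 structured residues: random
sequences are no less "structured" by this count. The predicted-region
composition bias recovers the annotated-region bias essentially perfectly
on synthetic data (`rep.pearson_bias["prnd_like|annotated|D"] == 1.000`),
and helix content in structured regions of the natural-like arm comes out
at `0.371 ± 0.092` (per-protein mean ± SD), matching the generator's
helix-enriched ordered-state emission.

The same comparison from the shell:

```bash
nullprot run -o report/            # default synthetic study
nullprot generate --model uniform --n 10000 --length 60 --seed 1 -o preq.fasta
nullprot score --in preq.fasta -o tracks.tsv
nullprot regions --tracks tracks.tsv -o regions.tsv
```

Every table lands as TSV next to a `report.json` that records seeds,
configuration hash and the conservation audit.

## Layout

```
src/nullprot/        library (seqgen, scoring, regions, composition,
                     secstruct, synthetic, pipeline, cli)
tests/               pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md      model/procedure details, defaults and limitations
```
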