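# Methods

## Problem and scope

`nullprot` compares databases of natural protein sequences against random
databases drawn from compositional null models, asking how the two differ in
predicted intrinsic disorder and secondary structure. The pipeline covers:
database construction (random generation under two composition models plus a
greedy sequence-identity redundancy screen), per-residue disorder scoring and
thresholding, run-length statistics of ordered/disordered regions,
amino-acid composition bias of region classes, and secondary-structure
content and segment-length statistics. External disorder and
secondary-structure predictors are treated as pluggable score providers; the
package neither reimplements nor requires them.

## Composition models

Two null models are built in. The *background* model uses the BLOSUM62
marginal target frequencies (Henikoff & Henikoff 1992) as the natural
occurrence rates of the 20 residue types; the published three-decimal values
are embedded as package data and sum to exactly 1.000. The *uniform* model
fixes every type at 5%. Random databases draw each position i.i.d. from the
model. Default database geometry is 10,000 sequences of 60 residues.

## Sequence identity and the redundancy screen

Identity between two sequences is defined on the optimal global
(Needleman–Wunsch) alignment under BLOSUM62 with affine gap penalties
(open 11, extend 1):

    identity = identical aligned columns / alignment length.

Optimal alignments are not unique, so the package takes, among all
score-optimal alignments, the one with the most identical columns, breaking
remaining ties by the fewest gap columns. Because this is a lexicographic
maximum over a set that does not depend on argument order, the identity is
symmetric and fully deterministic. It is computed in a single Gotoh dynamic
program by packing (score, matches, diagonal steps) into one integer key
that adds along alignment paths and compares lexicographically; the
numba-compiled kernel vectorizes over blocks of 64 sequences (~2 µs per
pair of 60-mers), which makes the ~5×10⁷ pairwise comparisons of a
10,000-sequence greedy screen take a few minutes on one CPU. Biopython's
`PairwiseAligner` with identical scoring is the independent oracle in the
test suite (exact score agreement, and match counts checked against the
enumerated set of optimal alignments).

The redundancy screen is greedy incremental clustering in input order: a
sequence is retained iff its identity to every previously retained sequence
is below the cutoff (default 30%). During random generation, a colliding
draw is discarded and replaced, capped at 1000·n total draws, so screened
random databases reach their nominal size exactly. Ties at the cutoff count
as redundant. For unrelated random 60-mers the alignment identity
distribution sits near 0.14 (max observed ≈ 0.28 over thousands of pairs),
so collisions at 30% are rare but not impossible; the screen verifies every
pair rather than assuming independence. A composition-intersection upper
bound is available as a prescreen but prunes almost nothing at a 30% cutoff;
throughput comes from the compiled kernel.

## Surrogate disorder predictor

The built-in surrogate maps each residue's TOP-IDP disorder propensity
(Campen et al. 2008) through a centered moving average (window 21, truncated
at the termini, no padding) and a logistic function
`1/(1 + exp(-slope · (mean - midpoint)))`. The midpoint (0.125) is halfway
between the glutamate and isoleucine propensities and the slope (3.6) is
calibrated so poly-E scores 0.90 and poly-I scores 0.10. The surrogate is
*not* a trained predictor: it only guarantees the correct sign behaviour
(disorder-promoting composition scores above 0.5) and monotonicity in
propensity, which is all the synthetic tests require. Per-residue scores
from real predictors can be supplied as TSV instead.

Binarization labels a residue disordered (D) when its score is at or above
the threshold (default 0.5); the tie at exactly 0.5 counts as disordered —
a fixed rule chosen because the underlying convention is ambiguous.

## Region statistics

Per sequence the package reports the number of disordered residues and the
longest contiguous disordered/structured run (first-occurring span on
ties). Three headline flags follow the conventions used when comparing
databases: *fully disordered* (longest D run spans the sequence), *nearly
fully structured* (at most 5 disordered residues), and *≥55 structured
residues* (length − disordered count ≥ 55). Dataset distributions are raw
integer histograms (no smoothing) reported as log2 counts with zero bins
suppressed. For variability estimates a dataset is split into k random
equal subsets (default 5; the split requires divisibility and is seeded);
per-bin means and standard deviations across subsets are reported, and the
plotted quantity is log2(mean × k), i.e. the subset mean restored to the
full-dataset scale.

## Composition bias

For region class r (ordered or disordered), the preference of residue type
i is ΔP_i = (P_i^r − P_i^all)/P_i^all where P_i^r pools residues of that
class across the whole database and P_i^all pools every residue of the
database (a pooled count, not a per-protein average). Two identities hold
by construction and are enforced as invariants: ΔP_i ≥ −1 with equality iff
type i is absent from the class, and Σ_i P_i^all·ΔP_i = 0. Annotated
regions (DisProt-style TSV, 1-based inclusive coordinates, validated for
overlap and bounds) are processed identically. Bias vectors are compared by
Pearson correlation (scipy).

## Secondary structure

Eight-state annotations reduce to three states by H,G,I → H; B,E → E;
T,S,coil → C, where both '-' and the 'D' token are accepted for coil.
Helix/sheet content is a per-protein fraction over the residues of one
region class (proteins without residues in a class are excluded from that
class), summarized as mean ± per-protein SD. Segments are maximal H or E
runs *within* a region class: a run crossing an order/disorder boundary is
split at the boundary, which keeps exact the conservation law that segment
lengths sum to the class's state residue count (the alternative —
assigning boundary runs by majority — would break it). Segment-length
tables report the fraction of a state's segments at each length as
log2(fraction × 10000); lengths supported by fewer than 5 distinct proteins
(configurable) are suppressed from reports but kept in raw output.
Databases are compared with Welch's unequal-variance t-test (two-sided),
implemented from the Welch formulas and cross-checked against
`scipy.stats.ttest_ind(equal_var=False)` to 1e-10 in the tests; Welch was
chosen over the pooled-variance test as the robust default since the
convention is otherwise unspecified.

## Synthetic study generator

The generator emulates the three-database design with known ground truth.
Each arm draws `n` sequences of length `L` (defaults 2000 and 60) tiled by
alternating ordered/disordered intervals with geometric lengths
(arm-specific means), plus an arm-specific probability that a sequence is
planted fully disordered. Defaults:

| arm        | background  | P(full disorder) | mean D len | mean O len |
|------------|-------------|------------------|------------|------------|
| pnat_like  | BLOSUM62    | 0.095            | 12         | 20         |
| prnd_like  | BLOSUM62    | 0.014            | 8          | 22         |
| preq_like  | uniform 5%  | 0.0              | 5          | 25         |

The full-disorder probabilities (9.5%, 1.4%, 0%) follow the prevalence
pattern observed when natural sequence databases are compared against
compositional null models — natural sets contain on the order of a hundred
times more fully disordered short sequences than uniform-composition random
sets — so the qualitative ordering of long-disorder prevalence across arms
holds by construction. Disordered intervals draw residues from the arm background
with D/E/K/R/S/P/Q enriched ×1.8 and W/C/F/I/Y/V depleted ×0.4
(renormalized) — the direction of compositional bias that disorder
predictors exploit; the multipliers are config-exposed. Score tracks are
the true 0/1 labels plus Gaussian noise (default SD 0.1) clipped to [0,1];
noise is generated as SD × a fixed standard-normal stream, so recovery
accuracy is exactly monotone in SD under a fixed seed. Secondary-structure
strings are emitted i.i.d. per residue from per-class 8-state
probabilities (helix-enriched in ordered regions), making segment lengths
geometric. All randomness derives from one master seed through
`numpy.random.SeedSequence` substreams per arm and component; outputs are
byte-reproducible.

The recorded truth (planted intervals, true labels, realized
disordered-region bias vector, emission parameters) supports field-by-field
recovery comparisons; `truth_report` emits truth tables in the same TSV
schemas as the analysis outputs.

What the generator does *not* emulate: evolutionary sequence profiles,
predictor-specific biases, position-dependent disorder structure (e.g.
terminal enrichment), or correlated secondary-structure emission. Passing
recovery tests therefore demonstrates the correctness of the statistical
machinery on data matching the generative assumptions, not predictor
accuracy on real proteins.

## Pipeline and audit

`run_comparison` executes score → binarize → region statistics →
composition bias → secondary-structure statistics per database and writes
every table as TSV plus `report.json` with run metadata (package version,
config hash, record counts). `validate_report` re-checks the conservation
laws (histogram totals equal dataset size, weighted bias sums vanish,
segment lengths conserve state counts, subset means restore the dataset
size); the CLI exits nonzero on any violation. Reports are byte-identical
for identical configuration and seed.

## Numerical choices and problem sizes

Frequency-sum validation uses a 1e-9 tolerance; the weighted-bias identity
is enforced at 1e-9 (it holds to machine precision); score tracks are
serialized with full `repr` precision so round trips are exact. The test
suite runs the full 10,000-sequence screened generation once per model (a
few minutes each) and otherwise uses 200–2000 sequences per arm, which is
ample for the recovery criteria (the bias-recovery correlation already
exceeds 0.95 at 300 sequences/arm).

## Known limitations

- The identity convention (global alignment, BLOSUM62 11/1, lexicographic
  tie-break) is a documented package choice; clustering tools define
  identity differently, so retained-set sizes are comparable only under
  this convention.
- The surrogate predictor is deliberately simple; its absolute scores are
  meaningful only relative to its own calibration.
- Annotated-region inputs are a minimal TSV dialect, not native DisProt
  exports.
- Secondary-structure emission is i.i.d. per residue; real helices/sheets
  have minimum lengths and cooperative structure.
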