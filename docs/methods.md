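# Methods

## Input representation and coordinates

A guide is represented by its 30-nt expanded target: upstream context
(labels −4…−1, array offsets 0–3), spacer (1…20, offsets 4–23), PAM
(21…23, offsets 24–26) and downstream context (+1…+3, offsets 27–29).
There is no label 0. Validation enforces length 30, the A/C/G/T
alphabet (lowercase is canonicalised; U is rejected because the
expanded target is genomic DNA), and `GG` at labels 22–23 (the NGG PAM
requirement of SpCas9). A permissive mode skips the PAM check for
exploratory featurisation of non-NGG sites; it is never used in
training.

## Features (149 = 93 numeric + 56 categorical)

* **GC fraction** of the 30-mer.
* **k-mer counts**, k = 1, 2, 3, overlapping windows over the 30-mer, in
  lexicographic order (4 + 16 + 64 features, named by the k-mer). Counts
  are raw integers, not proportions: within a fixed-length sequence the
  two are monotone-equivalent for tree splits, and integers are exactly
  testable (sums 30/29/28). A `proportions` flag provides the
  alternative.
* **Poly-T summaries**: the number of maximal T-runs of length ≥ 3, and
  the length of the longest maximal T-run. The longest run is reported
  unconditionally (values 1–2 occur), because the ≥ 3 threshold defines
  a *segment* while guide grouping by maximum run length needs the raw
  value; a `min_run_for_max=3` flag zeroes sub-threshold runs for the
  stricter convention. Either convention produces the same
  none / TTT / TTTT+ grouping.
* **Positional mononucleotides** at the 28 non-static labels, and
  **positional dinucleotides** keyed by start label for the 28 adjacent
  pairs excluding the static (22,23) pair. `di-1` spans the −1/1
  boundary, `di20` spans spacer end + PAM 'N', `di23` spans the
  PAM/downstream boundary. Both blocks are categorical with fixed
  vocabularies (4 and 16 levels), so category codes are stable across
  training and prediction and persisted with the model.
* **Melting temperatures** Tm1–Tm4 over labels 1–21, 1–4, 5–12 and
  16–20, computed by nearest-neighbor duplex thermodynamics
  (Biopython's `Tm_NN`) with the SantaLucia & Hicks (2004) unified
  DNA/DNA table, 50 mM Na⁺, 25 nM per strand, and the SantaLucia (1998)
  entropic salt correction. Nearest-neighbor is the natural choice here
  because it is the only standard Tm family sensitive to sequence
  *order*, which is what a positional feature set needs. Method and
  constants are configurable (`TmParameters`) and recorded in model
  provenance. The test suite checks the implementation against an
  independent re-derivation with hardcoded published constants to
  0.01 °C.
* **Folding energies**: ΔG of the transcribed 20-nt spacer, and of the
  spacer + 81-nt wild-type scaffold (101 nt), both at 37 °C. The engine
  is pluggable: the default shells out to `RNAfold` (one sequence per
  line in, `structure (energy)` line out, parsed exactly; values pinned
  in tests from ViennaRNA 2.7.2), and a deterministic hash-based stub
  keeps pipelines runnable and bit-reproducible where folding realism
  is irrelevant (training-pipeline tests, the acceptance script — the
  synthetic generator plants no folding effects, so the stub changes
  nothing being measured). ΔG ≤ 0 always; note ΔG(full) ≤ ΔG(spacer) is
  *not* an invariant and is deliberately not asserted.
* **Scaffold**: the canonical SpCas9 sgRNA scaffold (76-nt constant
  segment + 5 terminator U's, 81 nt). It is a config value; whatever
  scaffold is used is recorded in provenance.

## Harmonizing two screens

Guides are keyed by the full 30-mer (features live at that resolution;
a spacer+PAM fallback exists for inputs lacking context). The pipeline:
(1) merge the first screen's train/test tables, averaging duplicates
(unweighted — no weights are justified); (2) filter the second screen's
two assay days to ≥ 200 reads *per day*, then intersect and average;
(3) fit OLS of first-screen scores on second-screen scores over the
shared guides and rescale the second screen (direction fixed: the
second screen is adjusted to the first's scale); (4) merge with
duplicate averaging. Degenerate fits (< 2 pairs or constant source)
raise. All intermediate counts are reported. Merging is
order-invariant, and a positive-slope affine rescale preserves Spearman
correlations by construction.

## Training

LightGBM regression, MSE objective, categorical features native.
Deterministic settings (`deterministic=true`, `force_row_wise`, one
thread, fixed seeds) make retraining bit-identical. Ten-fold CV with a
fixed, seed-derived fold assignment shared by every hyperparameter
trial; each fit capped at 7,000 trees with `early_stopping_rounds=10`
on the held-out fold. Tuned parameters and bounds: learning rate
[0.005, 0.3] log-scale, max depth [3, 12], max bin [63, 511], leaves
[8, 256], feature and bagging fractions [0.5, 1.0] — conventional
well-behaved ranges for tabular regression at ~10³–10⁴ rows, all
configurable.

The Bayesian optimizer is an in-package Gaussian-process
expected-improvement loop (Matern-5/2 + white noise on the unit cube,
EI maximized over a random candidate pool, 10 initial points + 100
rounds by default, deterministic per seed). Failed objective
evaluations are recorded and skipped, not fatal.

The final model refits on all rows with
`n_trees = round(mean(per-fold best iterations))` (round-half-even).
Under MSE with mean-initialised boosting, the first tree's root
internal value is the training grand mean and later roots are 0; the
stored `base_value` is the exact training mean, since LightGBM's tree
dump serialises internal values at ~6 significant digits (tests check
the dumped root against the mean at 10⁻³ and the exact base value at
10⁻⁶). Both root properties are exact only without row subsampling
(with bagging each tree sees a subsample whose mean drifts slightly);
contract tests therefore fix `bagging_fraction=1`.

## Interpretation

Importance is the learner's recorded per-split objective gain summed
per feature and normalized to 1, descending with name tie-break. The
recorded gain for a split equals G_L²/H_L + G_R²/H_R − G²/H on the
boosting gradients, and at learning rate 1 the total equals the
achieved SSE reduction; a test recomputes this brute-force on a tiny
tree (agreement limited by LightGBM's float32 gain storage, checked at
rel. 10⁻⁴). Contributions use the learner's native `pred_contrib`
output (path-based); additivity `base + Σ contrib = prediction` is
exact to < 10⁻⁶ and asserted broadly. The same feature may contribute
differently for different guides, since contributions aggregate over
paths that depend on the other features. Tree export keeps categorical
splits as explicit category subsets (`di20 ∈ {…}`) and renders to
Graphviz DOT; plotting is optional and never touches data outputs.

## Evaluation statistics

Spearman = Pearson on mid-ranks (average ranks for ties); errors on
< 3 pairs or zero rank variance. Two predictors sharing an observed
variable are compared with Steiger's (1980) pooled-estimate Z
(Dunn–Clark covariance at the mean correlation), two-sided by default —
the reported significance convention does not state sidedness, so the
symmetric choice is the default with the one-sided value derivable from
z. Applying the test to Spearman rather than Pearson correlations is
an approximation, flagged in the output metadata; Monte-Carlo
calibration under a trivariate-normal null (n = 200, 2,000 replicates)
keeps the empirical type-I error near 0.05 and is part of the test
suite. External-screen evaluation supports training-overlap exclusion
and score reversal for negative-selection (log2 fold change) screens.

## Synthetic screens

The generator emulates what the pipeline assumes about real lentiviral
screens, with planted, analytically known effects: baseline 45 (the
observed mean efficiency of guides without poly-T in real screens is
~45); poly-T penalty −10 per unit of longest T-run above 2 (matching
the observed ~−10 for TTT and ~−25 for TTTT+ groups); a quadratic GC
optimum centred at 0.55 with curvature −80 (mild, a few score units
across the realistic GC range); positional dinucleotide offsets at
labels 18–20 with magnitudes (±2…7) taken from the scale of real
per-feature contributions, so di19/di18 matter; Gaussian noise SD 10;
clipping to [0, 100] with the clipped fraction logged. The paired
variant adds a second screen observing an affine transform
(a = −6, b = 1.25) of the same signal on two replicate days, a planted
overlap of 49 guides, and read counts falling below the 200-read filter
with probability 0.15.

What the generator does **not** emulate: real positional preferences
beyond the three planted labels, thermodynamic effects (Tm/ΔG carry no
planted signal), read-depth-dependent measurement error, chromatin or
cell-line effects, and guide-composition bias of designed libraries.
Passing the synthetic-recovery tests therefore shows that the pipeline
*recovers structure it is pointed at* — not that the defaults reach any
particular accuracy on real screens.

## Problem sizes and numerical choices

The test suite and acceptance script run reduced but honest sizes,
chosen as the package's own desk-scale defaults: end-to-end training
uses 5,000 guides (1,000 held out), a 300-tree cap and a 5-point
Bayesian search (3 initial + 2 guided); the importance-stability check
trains 10 independent 2,000-guide screens; the calibration study uses
2,000 replicates. The poly-T exhaustive check enumerates all 4⁸
length-8 sequences against a regex oracle. Ties in round-half-even tree
averaging, degenerate inputs (constant responses, split-free models,
empty datasets) and unseen categorical levels (mapped to missing with a
warning) all have defined, tested behaviour.

## Known limitations

NGG/SpCas9 only; no off-target scoring; no epigenetic features; no
DNA:RNA hybrid binding energy; full-scale accuracy claims require the
real screen data (see README's real-data recipe). The Steiger-on-
Spearman approximation and the LightGBM serialization precision limits
above are inherent to the chosen tooling.
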