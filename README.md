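# crisprboost

Interpretable prediction of wild-type CRISPR-Cas9 on-target cleavage
efficiency from sequence alone, for people designing or screening sgRNA
libraries who want to know not only *which* guides will cut well but
*why* the model thinks so.

## The problem and the model

The efficiency with which Cas9 cleaves a target varies strongly with the
guide sequence. `crisprboost` predicts the editing efficiency (indel %,
0–100 scale) of a guide from its **30-nt expanded target**: 4 nt of
upstream genomic context, the 20-nt spacer-matching protospacer, the
3-nt NGG PAM, and 3 nt of downstream context. Positions are labelled
relative to the spacer start: −4…−1 (upstream), 1…23 (spacer + PAM),
+1…+3 (downstream).

The predictor is a LightGBM gradient-boosted regression-tree ensemble
under squared-error loss over **149 features**:

* **93 numeric** — GC fraction; overlapping k-mer counts for k = 1, 2, 3
  over the whole 30-mer (4 + 16 + 64); the number of poly-T segments
  (maximal runs of ≥ 3 Ts, a Pol III termination signal that suppresses
  guide expression) and the longest T-run length; four nearest-neighbor
  melting temperatures Tm1–Tm4 over spacer regions 1–21, 1–4, 5–12 and
  16–20 (SantaLucia 2004 unified parameters); and two RNA-folding
  minimum free energies, ΔG of the transcribed 20-nt spacer and of the
  spacer joined to the 81-nt wild-type scaffold (RNAfold).
* **56 categorical** — the position-specific mononucleotide at each of
  28 labels and the position-specific dinucleotide at each of 28 start
  labels (the static GG of the PAM is dropped from both). These enter
  the trees **natively as categorical features** — no one-hot encoding —
  so a single split can group informative category subsets such as
  `di20 ∈ {AC, AG, GA, …}`.

Hyperparameters are tuned by Gaussian-process Bayesian optimization of
the 10-fold cross-validated MSE (same folds for every trial; up to
7,000 trees per fit with 10-round early stopping), and the final model
is refitted on all data with the tree count set to the rounded mean of
the per-fold early-stopped iteration counts.

Because boosting under MSE starts from the grand mean, every prediction
decomposes exactly as

```
prediction = training mean + Σ per-feature contributions
```

and the package exposes that decomposition, normalized gain importance
(fractions summing to 1), and tree exports whose internal values are
running branch means (root of tree 0 = grand mean; roots of later trees
= 0).

A harmonization module reproduces the standard recipe for combining two
overlapping screens measured on different scales: read-count filtering
(≥ 200 reads per day), replicate-day intersection averaging, OLS
rescaling fitted on the shared guides, and duplicate-averaged merging.
An evaluation module scores predictors by Spearman correlation and
compares two predictors on the same screen with Steiger's (1980) test
for dependent correlations.

## Worked example

`examples/01_featurize_sequence.py` featurizes one guide:

```
sequence  : GTCT-GCCATCTCTGATGGATGTGA-TGG-GCA
GC content: 0.5333  (fraction of G/C in the 30-mer)
poly-T    : 0 segment(s) of >=3 Ts, longest T-run = 1
di19=GA di18=TG di20=AT  (3'-end dinucleotides, the strongest positional predictors of cleavage efficiency)
Tm1..Tm4  : 51.64 -46.11 0.49 -36.35 degC
dG        : spacer -4.80, spacer+scaffold -25.60 kcal/mol (more negative = more stably folded guide)
feature record width: 149 (93 numeric + 56 categorical)
```

`examples/03_train_and_predict.py` trains on a 2,000-guide synthetic
screen (known planted effects, noise SD 10) and prints:

```
final model: 191 trees (mean of per-fold early-stopped iteration counts)
base value : 41.1039 = training grand mean
held-out Spearman vs observed scores : 0.422
held-out Spearman vs noiseless signal: 0.814
```

The model ranks held-out guides close to their true planted activity;
the correlation with *observed* scores is much lower because the
measurement noise caps it. `examples/04_interpret_model.py` then shows
the poly-T features dominating the importance table and a per-guide
additive contribution breakdown; `examples/02_harmonize_screens.py` and
`examples/05_compare_predictors.py` demonstrate cross-screen rescaling
and the dependent-correlation test.

There is also a thin CLI mirroring the library
(`crisprboost featurize | harmonize | train | predict | interpret |
evaluate | compare | simulate`).

## Training on real screens

The packaged generator stands in for two published lentiviral HEK293T
screen datasets that cannot be redistributed here. To train the
full-scale model: obtain the two screens' supplementary tables (train +
test tables of the first; Day 8 / Day 10 doxycycline-negative tables of
the second), convert them to TSV with columns
`sequence30, efficiency, reads`, run `crisprboost harmonize` (49
overlapping guides drive the rescaling), then `crisprboost train` with
the full search budget (`--n-init 10 --n-iter 100`). When evaluating on
external benchmark screens, drop guides overlapping the training set
(`--exclude`) and sign-reverse log2-fold-change dropout screens
(`--reverse`).
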