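"""Compare two predictors on one screen with Steiger's dependent-correlation test.

Both predictors are scored against the same observed efficiencies, so
their Spearman correlations are dependent; Steiger's (1980) Z accounts
for the correlation between the two prediction vectors.
"""

import numpy as np

import crisprboost as cb

rng = np.random.default_rng(0)
n = 400
truth = rng.uniform(0, 100, n)
observed = truth + rng.normal(0, 15, n)
pred_good = truth + rng.normal(0, 10, n)   # sharper predictor
pred_weak = truth + rng.normal(0, 30, n)   # noisier predictor

comp = cb.compare_predictors(observed, pred_good, pred_weak)
print(f"n = {comp.n}")
print(f"Spearman(A, observed) = {comp.r_model_A:.3f}")
print(f"Spearman(B, observed) = {comp.r_model_B:.3f}")
print(f"Spearman(A, B)        = {comp.r_AB:.3f}")
print(f"Steiger Z = {comp.z:.3f}, two-sided p = {comp.p:.2e}")
print("A small p means the two predictors' correlations with the observed")
print("scores genuinely differ, after accounting for their shared information.")
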