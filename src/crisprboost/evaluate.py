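"""Evaluation: rank correlation and dependent-correlation comparison.

Predictors of guide efficiency are scored with Spearman correlation
against measured efficiencies (the task is a ranking task, and measured
scores relate non-linearly to predictions).  Two predictors evaluated on
the same guides yield dependent correlations sharing the observed
variable; their difference is tested with Steiger's (1980) Z for
dependent correlations, applied to the Spearman values — an approximate
but field-standard usage, noted in the output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import featurize_frame
from .model import TrainedModel, predict
from .targets import validate_target
from .thermo import FoldingEngine, ScaffoldConfig, TmParameters, compute_thermo_many

__all__ = [
    "spearman",
    "steiger_test",
    "CorrelationComparison",
    "compare_predictors",
    "evaluate_dataset",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Raises on length mismatch, fewer than
    3 pairs, or zero rank variance in either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    ``r_jk`` and ``r_jh`` are the correlations being compared (e.g. each
    predictor vs observed efficiency); ``r_kh`` is the correlation
    between the two non-shared variables (the two prediction vectors).
    Uses the pooled-estimate form: Fisher-z difference scaled by the
    Dunn & Clark covariance evaluated at the mean correlation.  Returns
    (z, two-sided p).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
        if abs(r) == 1.0 and name != "r_kh":
            raise ValueError(f"{name}=+/-1 degenerates the Fisher-z transform")
    if r_kh == 1.0 and r_jk == r_jh:
        return 0.0, 1.0
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    r_bar = (r_jk + r_jh) / 2.0
    rb2 = r_bar * r_bar
    psi = r_kh * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_kh * r_kh)
    s_bar = psi / ((1 - rb2) ** 2)
    denom = 2.0 - 2.0 * s_bar
    if denom <= 0:
        raise ValueError("degenerate correlation triple (covariance >= variance)")
    z = math.sqrt(n - 3) * (z_jk - z_jh) / math.sqrt(denom)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


@dataclass(frozen=True)
class CorrelationComparison:
    """Head-to-head comparison of two predictors on shared guides."""

    r_model_A: float
    r_model_B: float
    r_AB: float
    n: int
    z: float
    p: float
    note: str = (
        "Steiger Z applied to Spearman correlations (approximate; "
        "test derived for Pearson)"
    )

    def as_dict(self) -> dict:
        return {
            "r_model_A": self.r_model_A,
            "r_model_B": self.r_model_B,
            "r_AB": self.r_AB,
            "n": self.n,
            "z": self.z,
            "p": self.p,
            "note": self.note,
        }


def compare_predictors(observed, pred_A, pred_B) -> CorrelationComparison:
    """Spearman both predictors against observations and test the difference."""
    r_a = spearman(pred_A, observed)
    r_b = spearman(pred_B, observed)
    r_ab = spearman(pred_A, pred_B)
    n = len(np.asarray(observed))
    z, p = steiger_test(r_a, r_b, r_ab, n)
    return CorrelationComparison(r_a, r_b, r_ab, n, z, p)


def evaluate_dataset(
    model: TrainedModel,
    dataset: pd.DataFrame,
    *,
    engine: FoldingEngine,
    reverse_scores: bool = False,
    exclusion_set: set[str] | frozenset[str] | None = None,
    tm_params: TmParameters | None = None,
    scaffold: ScaffoldConfig | None = None,
) -> tuple[int, float]:
    """Score a model on an external screen.

    ``dataset`` needs columns ``sequence30`` and ``efficiency``.  Guides
    whose 30-mer appears in ``exclusion_set`` (typically the training
    set) are dropped before scoring; ``reverse_scores`` negates observed
    values for negative-selection screens where lower log2 fold change
    means stronger cleavage.  Returns ``(n_used, Spearman)``.
    """
    frame = dataset.copy()
    if exclusion_set:
        frame = frame[~frame["sequence30"].isin(exclusion_set)]
    if len(frame) < 3:
        raise InsufficientDataError(
            f"only {len(frame)} guides remain after exclusion; need >= 3"
        )
    observed = frame["efficiency"].to_numpy(dtype=float)
    if reverse_scores:
        observed = -observed
    targets = [validate_target(s) for s in frame["sequence30"]]
    thermos = compute_thermo_many(
        targets, tm_params=tm_params, scaffold=scaffold, engine=engine
    )
    X = featurize_frame(targets, thermos)
    pred = predict(model, X)
    return len(frame), spearman(pred, observed)
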