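"""Boosted-regression-tree training with fixed-fold CV and Bayesian tuning.

The learner is LightGBM regression under squared-error loss, consuming
categorical features natively (no one-hot encoding): position-specific
mono- and dinucleotides enter as pandas categoricals with fixed
vocabularies so category codes are stable between training and
prediction.  Hyperparameters are tuned by Bayesian optimization of the
10-fold cross-validated MSE, with the same fold assignment reused for
every trial; each fit is capped at 7,000 trees with early stopping
(10 rounds) on the held-out fold.  The final model is refitted on all
rows with the tree count set to the rounded mean of the per-fold best
iterations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats

from .bayesopt import ParamSpace, bayesian_optimize
from .features import SCHEMA, FeatureSchema, SchemaError

__all__ = [
    "HyperParams",
    "CVConfig",
    "TrainedModel",
    "DEFAULT_SEARCH_SPACE",
    "make_folds",
    "cv_evaluate",
    "tune_hyperparameters",
    "train_final",
    "predict",
    "conform_features",
]


@dataclass(frozen=True)
class HyperParams:
    learning_rate: float = 0.05
    max_depth: int = 8
    max_bin: int = 255
    num_leaves: int = 63
    feature_fraction: float = 0.9
    bagging_fraction: float = 0.9

    def to_lgb(self) -> dict:
        p = {
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "max_bin": self.max_bin,
            "num_leaves": self.num_leaves,
            "feature_fraction": self.feature_fraction,
            "bagging_fraction": self.bagging_fraction,
        }
        if self.bagging_fraction < 1.0:
            p["bagging_freq"] = 1
        return p


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 10
    fold_seed: int = 2022
    max_trees: int = 7000
    early_stopping_rounds: int = 10
    train_seed: int = 1


#: Search bounds for the tuned hyperparameters; standard well-behaved
#: ranges for ~24k-row tabular regression, all overridable.
DEFAULT_SEARCH_SPACE: list[ParamSpace] = [
    ParamSpace("learning_rate", 0.005, 0.3, "logfloat"),
    ParamSpace("max_depth", 3, 12, "int"),
    ParamSpace("max_bin", 63, 511, "int"),
    ParamSpace("num_leaves", 8, 256, "int"),
    ParamSpace("feature_fraction", 0.5, 1.0, "float"),
    ParamSpace("bagging_fraction", 0.5, 1.0, "float"),
]


@dataclass
class TrainedModel:
    """A fitted ensemble plus everything needed to reapply it faithfully."""

    booster: lgb.Booster
    schema: FeatureSchema
    n_trees_used: int
    base_value: float
    provenance: dict = field(default_factory=dict)

    def save(self, model_path: str | Path) -> None:
        """Write the booster text format plus a JSON sidecar next to it."""
        model_path = Path(model_path)
        model_path.write_text(self.booster.model_to_string())
        sidecar = {
            "schema": json.loads(self.schema.to_json()),
            "n_trees_used": self.n_trees_used,
            "base_value": self.base_value,
            "provenance": self.provenance,
        }
        model_path.with_suffix(model_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, default=str)
        )

    @classmethod
    def load(cls, model_path: str | Path) -> "TrainedModel":
        model_path = Path(model_path)
        booster = lgb.Booster(model_str=model_path.read_text())
        sidecar = json.loads(
            model_path.with_suffix(model_path.suffix + ".json").read_text()
        )
        return cls(
            booster=booster,
            schema=FeatureSchema.from_json(json.dumps(sidecar["schema"])),
            n_trees_used=sidecar["n_trees_used"],
            base_value=sidecar["base_value"],
            provenance=sidecar.get("provenance", {}),
        )


def _base_lgb_params(seed: int) -> dict:
    return {
        "objective": "regression",
        "metric": "l2",
        "verbosity": -1,
        "num_threads": 1,
        "deterministic": True,
        "force_row_wise": True,
        "seed": seed,
    }


def conform_features(frame: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Reorder/retype a feature table to a schema; unseen levels become missing.

    Values of a categorical column outside the registered vocabulary are
    mapped to missing (the learner's documented fallback path) with a
    warning.
    """
    schema.validate_frame(frame)
    out = frame[list(schema.names)].copy()
    for name in schema.numeric:
        out[name] = out[name].astype(float)
    for name in schema.categorical:
        vocab = list(schema.vocabularies[name])
        col = pd.Categorical(out[name], categories=vocab)
        n_lost = int(pd.isna(col).sum() - out[name].isna().sum())
        if n_lost > 0:
            warnings.warn(
                f"{n_lost} value(s) in {name!r} outside the registered "
                f"vocabulary; treated as missing",
                stacklevel=2,
            )
        out[name] = col
    return out


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic partition of ``range(n)`` into k near-equal folds."""
    if not (2 <= k <= n):
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % k
    return folds


def _fit_one(X, y, params: HyperParams, cv: CVConfig, valid=None, num_rounds=None):
    lgb_params = _base_lgb_params(cv.train_seed) | params.to_lgb()
    train_set = lgb.Dataset(X, label=y, params={"verbosity": -1})
    callbacks = []
    valid_sets = []
    if valid is not None:
        valid_sets = [lgb.Dataset(valid[0], label=valid[1], reference=train_set)]
        callbacks.append(
            lgb.early_stopping(cv.early_stopping_rounds, verbose=False)
        )
    booster = lgb.train(
        lgb_params,
        train_set,
        num_boost_round=num_rounds or cv.max_trees,
        valid_sets=valid_sets or None,
        callbacks=callbacks or None,
    )
    return booster


def cv_evaluate(
    features: pd.DataFrame,
    y: np.ndarray,
    params: HyperParams,
    cv: CVConfig,
    folds: np.ndarray | None = None,
) -> tuple[float, float, list[int]]:
    """K-fold CV of one hyperparameter combination.

    Returns (mean validation MSE, mean validation Spearman, per-fold
    best-iteration list).  Fold assignment is deterministic from
    ``cv.fold_seed`` and identical across calls unless supplied.
    """
    X = conform_features(features, SCHEMA if features.shape[1] == SCHEMA.width else _infer_schema(features))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise SchemaError(f"{len(X)} feature rows vs {len(y)} responses")
    if folds is None:
        folds = make_folds(len(y), cv.k_folds, cv.fold_seed)
    mses, rhos, best_iters = [], [], []
    for f in range(cv.k_folds):
        val_mask = folds == f
        val_idx = np.flatnonzero(val_mask)
        train_idx = np.flatnonzero(~val_mask)
        assert not np.intersect1d(val_idx, train_idx).size, "CV fold leakage"
        X_tr, y_tr = X[~val_mask], y[~val_mask]
        X_va, y_va = X[val_mask], y[val_mask]
        booster = _fit_one(X_tr, y_tr, params, cv, valid=(X_va, y_va))
        best_iter = booster.best_iteration or booster.num_trees()
        pred = booster.predict(X_va, num_iteration=best_iter)
        mses.append(float(np.mean((pred - y_va) ** 2)))
        if np.ptp(y_va) > 0 and np.ptp(pred) > 0:
            rhos.append(float(stats.spearmanr(pred, y_va).statistic))
        best_iters.append(int(best_iter))
    return float(np.mean(mses)), float(np.mean(rhos)) if rhos else float("nan"), best_iters


def _infer_schema(frame: pd.DataFrame) -> FeatureSchema:
    # Fallback for non-standard feature tables (tests with toy features):
    # categoricals are taken from pandas dtype, vocabularies from categories.
    numeric, categorical, vocab = [], [], {}
    for name in frame.columns:
        if isinstance(frame[name].dtype, pd.CategoricalDtype):
            categorical.append(name)
            vocab[name] = tuple(frame[name].cat.categories)
        else:
            numeric.append(name)
    return FeatureSchema(tuple(numeric), tuple(categorical), vocab)


def tune_hyperparameters(
    features: pd.DataFrame,
    y: np.ndarray,
    cv: CVConfig | None = None,
    space: list[ParamSpace] | None = None,
    n_init: int = 10,
    n_iter: int = 100,
    seed: int = 7,
):
    """Bayesian search over hyperparameters, maximizing negative CV MSE.

    Returns ``(best HyperParams, best per-fold iterations, trace)``.
    The fold assignment is computed once and shared by every trial.
    """
    cv = cv or CVConfig()
    space = space or DEFAULT_SEARCH_SPACE
    folds = make_folds(len(y), cv.k_folds, cv.fold_seed)
    cache: dict[tuple, list[int]] = {}

    def objective(params: dict) -> float:
        hp = HyperParams(**params)
        mse, _, best_iters = cv_evaluate(features, y, hp, cv, folds=folds)
        cache[tuple(sorted(params.items()))] = best_iters
        return -mse

    result = bayesian_optimize(
        objective, space, n_init=n_init, n_iter=n_iter, seed=seed
    )
    best_hp = HyperParams(**result.best_params)
    best_iters = cache[tuple(sorted(result.best_params.items()))]
    return best_hp, best_iters, result.trace


def train_final(
    features: pd.DataFrame,
    y: np.ndarray,
    params: HyperParams,
    per_fold_best_iterations: list[int],
    cv: CVConfig | None = None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit on all rows with the tree count averaged from CV.

    ``n_trees_used = round(mean(per-fold best iterations))`` with
    round-half-even.  The model's base value is read back from the first
    tree's root internal value, which equals the training grand mean
    under squared-error loss.
    """
    if not per_fold_best_iterations:
        raise ValueError("per-fold best-iteration list is empty")
    cv = cv or CVConfig()
    n_trees = int(round(float(np.mean(per_fold_best_iterations))))
    n_trees = max(n_trees, 1)
    schema = SCHEMA if features.shape[1] == SCHEMA.width else _infer_schema(features)
    X = conform_features(features, schema)
    y = np.asarray(y, dtype=float)
    booster = _fit_one(X, y, params, cv, num_rounds=n_trees)
    # Under squared-error loss with mean-initialised boosting the first
    # tree's root internal value is the training grand mean; store the
    # exact mean (the dump serialises internal values at ~6 significant
    # digits, too coarse for the additivity contract).
    base_value = float(np.mean(y))
    prov = {
        "hyperparams": asdict(params),
        "cv": asdict(cv),
        "n_rows": int(len(y)),
        "per_fold_best_iterations": list(map(int, per_fold_best_iterations)),
    }
    if provenance:
        prov.update(provenance)
    return TrainedModel(
        booster=booster,
        schema=schema,
        n_trees_used=n_trees,
        base_value=base_value,
        provenance=prov,
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted efficiency scores, one finite value per row."""
    X = conform_features(features, model.schema)
    pred = model.booster.predict(X)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite prediction produced")
    return pred
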