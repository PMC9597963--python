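"""Gaussian-process Bayesian optimization for hyperparameter search.

A compact sequential model-based optimizer: after ``n_init`` uniform
random evaluations, each round fits a Matern-5/2 Gaussian process to the
observed (params, score) pairs on the unit hypercube and proposes the
candidate maximizing expected improvement over a random candidate pool.
Maximization convention: the objective returns a score to be maximized
(use a negated loss for minimization).  Deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["ParamSpace", "BOResult", "bayesian_optimize", "OptimizationError"]


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ParamSpace:
    """One search dimension.

    kind: 'float' (uniform), 'logfloat' (uniform in log10), or 'int'
    (uniform integer, inclusive bounds).
    """

    name: str
    low: float
    high: float
    kind: str = "float"

    def __post_init__(self):
        if self.kind not in ("float", "logfloat", "int"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError(f"bad bounds for {self.name}: [{self.low}, {self.high}]")
        if self.kind == "logfloat" and self.low <= 0:
            raise ValueError(f"logfloat bounds must be positive for {self.name}")

    def from_unit(self, u: float):
        u = min(max(u, 0.0), 1.0)
        if self.kind == "logfloat":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return 10 ** (lo + u * (hi - lo))
        val = self.low + u * (self.high - self.low)
        if self.kind == "int":
            return int(round(val))
        return val


@dataclass
class BOResult:
    best_params: dict
    best_score: float
    trace: list = field(default_factory=list)  # (params, score | None)


def _expected_improvement(mu, sigma, best, xi=0.01):
    sigma = np.maximum(sigma, 1e-12)
    imp = mu - best - xi
    z = imp / sigma
    return imp * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayesian_optimize(
    objective,
    space: list[ParamSpace],
    n_init: int = 10,
    n_iter: int = 100,
    seed: int = 0,
    n_candidates: int = 2000,
) -> BOResult:
    """Maximize ``objective(params_dict)`` over the search space.

    A failing objective evaluation (any exception) is recorded in the
    trace with score ``None`` and excluded from the surrogate; the
    search continues.  If every evaluation fails, raises
    :class:`OptimizationError`.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    d = len(space)

    units: list[np.ndarray] = []
    scores: list[float | None] = []
    trace: list[tuple[dict, float | None]] = []

    def to_params(u: np.ndarray) -> dict:
        return {dim.name: dim.from_unit(float(ui)) for dim, ui in zip(space, u)}

    def evaluate(u: np.ndarray) -> None:
        params = to_params(u)
        try:
            score = float(objective(params))
        except Exception as exc:  # noqa: BLE001 - point failure is recoverable
            warnings.warn(f"objective failed at {params}: {exc}", stacklevel=2)
            score = None
        units.append(u)
        scores.append(score)
        trace.append((params, score))

    for _ in range(n_init):
        evaluate(rng.random(d))

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5) + WhiteKernel(
        noise_level=1e-4, noise_level_bounds=(1e-8, 1e1)
    )
    for _ in range(n_iter):
        ok = [i for i, s in enumerate(scores) if s is not None]
        if ok:
            X = np.array([units[i] for i in ok])
            y = np.array([scores[i] for i in ok])
            y_mean, y_sd = y.mean(), y.std()
            yn = (y - y_mean) / y_sd if y_sd > 0 else y - y_mean
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=False,
                alpha=1e-8,
                n_restarts_optimizer=1,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X, yn)
            cand = rng.random((n_candidates, d))
            mu, sigma = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sigma, yn.max())
            u_next = cand[int(np.argmax(ei))]
        else:
            u_next = rng.random(d)
        evaluate(u_next)

    ok = [i for i, s in enumerate(scores) if s is not None]
    if not ok:
        raise OptimizationError("every objective evaluation failed")
    best_i = max(ok, key=lambda i: scores[i])
    return BOResult(
        best_params=to_params(units[best_i]),
        best_score=float(scores[best_i]),
        trace=trace,
    )
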