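"""Multi-response desirability optimization and prediction intervals.

Each predicted response is mapped to an individual desirability
``d in [0, 1]`` by the Derringer-Suich ramps (minimize / maximize / target /
in-range, with optional hard constraint bounds that zero the desirability
outright).  The overall desirability is the importance-weighted geometric
mean

.. math::

    D = \\Big(\\prod_i d_i^{r_i}\\Big)^{1/\\sum_i r_i},

maximized over the coded design cube ``[-1, 1]^3`` by deterministic
multistart Nelder-Mead seeded from a coarse grid, with an exhaustive grid
fallback so the answer is reproducible run-to-run.

Prediction intervals for a single future observation use the standard OLS
form ``yhat +/- t * s * sqrt(1 + x'(X'X)^{-1}x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .rsm import RSMResults

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "PredictionInterval",
    "desirability",
    "overall_desirability",
    "optimize_desirability",
    "predict_interval",
    "percent_error",
    "NoFeasiblePointError",
]


class NoFeasiblePointError(RuntimeError):
    """Raised when overall desirability is zero everywhere on the cube."""


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal specification for one response.

    Parameters
    ----------
    response : str
        Response name (must match a fitted model).
    kind : {"minimize", "maximize", "target", "in_range"}
    lower, upper : float
        Ramp anchors in response units (``lower < upper``).  For
        ``minimize`` d = 1 at/below ``lower`` and 0 at/above ``upper``;
        ``maximize`` is mirrored; ``target`` ramps up to ``target`` then
        back down; ``in_range`` is the 0/1 indicator of [lower, upper].
    target : float, optional
        Required for ``kind="target"``.
    weight : float
        Ramp exponent (1 = linear).
    importance : float
        Exponent in the geometric mean.
    constraint_upper, constraint_lower : float, optional
        Hard acceptance bounds; a predicted value at/beyond the bound gets
        d = 0 (e.g. particle size <= 200 nm means ``constraint_upper=200``).
    """

    response: str
    kind: str
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0
    constraint_upper: float | None = None
    constraint_lower: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("minimize", "maximize", "target", "in_range"):
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("anchors must be finite")
        if not self.lower < self.upper:
            raise ValueError("lower anchor must be < upper anchor")
        if self.kind == "target" and self.target is None:
            raise ValueError("target goal needs a target value")


def desirability(value: float, goal: DesirabilityGoal) -> float:
    """Individual desirability of one predicted value under one goal."""
    v = float(value)
    if goal.constraint_upper is not None and v >= goal.constraint_upper:
        return 0.0
    if goal.constraint_lower is not None and v <= goal.constraint_lower:
        return 0.0
    lo, hi, w = goal.lower, goal.upper, goal.weight
    if goal.kind == "minimize":
        if v <= lo:
            return 1.0
        if v >= hi:
            return 0.0
        return ((hi - v) / (hi - lo)) ** w
    if goal.kind == "maximize":
        if v >= hi:
            return 1.0
        if v <= lo:
            return 0.0
        return ((v - lo) / (hi - lo)) ** w
    if goal.kind == "target":
        t = goal.target
        if v <= lo or v >= hi:
            return 0.0
        if v <= t:
            return ((v - lo) / (t - lo)) ** w
        return ((hi - v) / (hi - t)) ** w
    # in_range
    return 1.0 if lo <= v <= hi else 0.0


def overall_desirability(ds, importances=None) -> float:
    """Importance-weighted geometric mean of individual desirabilities."""
    ds = np.asarray(ds, dtype=float)
    if importances is None:
        importances = np.ones_like(ds)
    r = np.asarray(importances, dtype=float)
    if np.any(ds == 0.0):
        return 0.0
    return float(np.exp(np.sum(r * np.log(ds)) / np.sum(r)))


@dataclass
class OptimizationResult:
    """Optimum located by :func:`optimize_desirability`."""

    coded: np.ndarray
    actual: dict
    predicted: dict
    desirabilities: dict
    overall: float
    trace: list = field(default_factory=list)

    def rounded_actual(self, decimals: dict | None = None) -> dict:
        """Actual settings rounded per-factor (defaults to 2 decimals)."""
        decimals = decimals or {}
        return {k: round(v, decimals.get(k, 2)) for k, v in self.actual.items()}


def _objective(point, fits, goals):
    preds = {g.response: float(f.predict(point)[0]) for f, g in zip(fits, goals)}
    ds = {g.response: desirability(preds[g.response], g) for g in goals}
    D = overall_desirability(list(ds.values()), [g.importance for g in goals])
    return preds, ds, D


def optimize_desirability(
    fits: list[RSMResults],
    goals: list[DesirabilityGoal],
    seed: int = 0,
    n_grid: int = 21,
    n_starts: int = 10,
) -> OptimizationResult:
    """Maximize overall desirability over the coded cube ``[-1, 1]^3``.

    A full ``n_grid^3`` evaluation grid seeds ``n_starts`` Nelder-Mead
    polishes (bounded to the cube); the best point wins, with ties broken
    by larger D then smaller predicted first response.  Entirely
    deterministic for fixed arguments; ``seed`` is accepted for interface
    symmetry with the stochastic generators.

    Raises
    ------
    NoFeasiblePointError
        If D = 0 everywhere on the evaluation grid.
    """
    if len(fits) != len(goals):
        raise ValueError("need exactly one fitted model per goal")
    k = len(fits[0].design.factors)

    axes = [np.linspace(-1.0, 1.0, n_grid)] * k
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    Dgrid = np.empty(len(mesh))
    for i, pt in enumerate(mesh):
        Dgrid[i] = _objective(pt, fits, goals)[2]
    if np.all(Dgrid == 0.0):
        raise NoFeasiblePointError("overall desirability is zero over the whole cube")

    order = np.argsort(-Dgrid, kind="stable")[:n_starts]
    trace = []

    def neg(x):
        return -_objective(np.clip(x, -1.0, 1.0), fits, goals)[2]

    best = None
    for i in order:
        res = minimize(
            neg,
            mesh[i],
            method="Nelder-Mead",
            bounds=[(-1.0, 1.0)] * k,
            options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000},
        )
        x = np.clip(res.x, -1.0, 1.0)
        preds, ds, D = _objective(x, fits, goals)
        trace.append({"start": mesh[i].tolist(), "x": x.tolist(), "D": D})
        key = (D, -preds[goals[0].response])
        if best is None or key > best[0]:
            best = (key, x, preds, ds, D)

    _, x, preds, ds, D = best
    factors = fits[0].design.factors
    actual = {f.name: float(f.to_actual(x[j])) for j, f in enumerate(factors)}
    return OptimizationResult(
        coded=x, actual=actual, predicted=preds, desirabilities=ds,
        overall=D, trace=trace,
    )


@dataclass(frozen=True)
class PredictionInterval:
    """Interval for one future observation at a coded point."""

    point: float
    lower: float
    upper: float
    leverage: float
    level: float


def predict_interval(fit: RSMResults, point, level: float = 0.95) -> PredictionInterval:
    """Prediction interval ``yhat +/- t * s * sqrt(1 + leverage)``.

    ``s^2`` is the residual mean square and ``t`` the two-sided quantile of
    Student's t with the fit's residual df.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if fit.df_resid <= 0:
        raise ZeroDivisionError("no residual degrees of freedom: interval undefined")
    yhat = float(fit.predict(point)[0])
    lev = fit.leverage(point)
    s = np.sqrt(fit.sigma2)
    t = stats.t.ppf((1.0 + level) / 2.0, fit.df_resid)
    half = t * s * np.sqrt(1.0 + lev)
    return PredictionInterval(yhat, yhat - half, yhat + half, lev, level)


def percent_error(observed: float, predicted: float) -> float:
    """Signed percent deviation, ``(observed - predicted)/predicted * 100``."""
    if predicted == 0:
        raise ZeroDivisionError("percent error undefined for predicted = 0")
    return (observed - predicted) / predicted * 100.0
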