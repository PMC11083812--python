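"""Drug-release curves: cumulative release with sampling correction and
kinetic model fitting/selection.

In a dialysis release experiment an aliquot of volume ``Ve`` is withdrawn
at each timepoint and replaced with fresh medium, so the measured
concentration underestimates what has actually been released.  The standard
correction is

.. math::

    CR_n(\\%) = \\frac{V_e \\sum_{i=1}^{n-1} C_i + V_o C_n}{m} \\times 100

where ``Vo`` is the vessel volume, ``C_i`` the measured concentration at
timepoint ``i`` (mg/mL) and ``m`` the total drug in the bag (mg).

Five empirical kinetic models are supported, all expressed on the
cumulative-percent scale ``F(t)``:

====================  =======================================  ==========
model id              form                                     parameters
====================  =======================================  ==========
``zero_order``        ``F = K0 * t``                           K0
``first_order``       ``F = 100 * (1 - exp(-K1 * t))``         K1
``higuchi``           ``F = KH * sqrt(t)``                     KH
``korsmeyer_peppas``  ``F = KKP * t**n``                       KKP, n
``hixson_crowell``    ``F = 100 - (100**(1/3) - KHC*t)**3``    KHC
====================  =======================================  ==========

First-order and Hixson-Crowell are anchored at 100 % release at infinite
time (one free parameter each).  Fits are nonlinear least squares on the
untransformed percents, started from linearized estimates (log-log for
Korsmeyer-Peppas).  Model comparison uses R^2, the unweighted
``AIC = n*ln(SSR) + 2p`` and the model selection criterion
``MSC = ln(SST/SSR) - 2p/n``; higher MSC (equivalently lower AIC at fixed
n) wins, and the Korsmeyer-Peppas exponent classifies the transport
mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ReleaseCurve",
    "KineticFitResult",
    "ReleaseKineticsModel",
    "MODELS",
    "cumulative_release",
    "fit_kinetic",
    "fit_all_models",
    "information_criteria",
    "classify_exponent",
    "select_model",
    "ModelSelectionError",
]


class ModelSelectionError(RuntimeError):
    """Raised when no converged candidate fits are available."""


@dataclass
class ReleaseCurve:
    """A release time course plus the vessel/sampling geometry.

    Either measured concentrations ``conc`` (mg/mL) or ready-made
    cumulative percents ``cr`` may be supplied.
    """

    times: np.ndarray
    conc: np.ndarray | None = None
    cr: np.ndarray | None = None
    Ve: float = 1.0
    Vo: float = 200.0
    m: float = 1.0
    cr_tolerance: float = 2.0  # assay noise may push CR slightly past 100 %

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.Ve < 0:
            raise ValueError("sampling volume Ve must be >= 0")
        if self.Vo <= 0:
            raise ValueError("vessel volume Vo must be > 0")
        if self.m <= 0:
            raise ValueError("total drug mass m must be > 0")
        if self.conc is not None:
            self.conc = np.asarray(self.conc, dtype=float)
            if np.any(self.conc < 0):
                raise ValueError("concentrations must be non-negative")
        if self.cr is not None:
            self.cr = np.asarray(self.cr, dtype=float)
            if np.any(self.cr > 100.0 + self.cr_tolerance) or np.any(self.cr < 0):
                raise ValueError("cumulative release outside [0, 100] beyond tolerance")

    def cumulative(self) -> np.ndarray:
        """Cumulative percent released (computes from ``conc`` if needed)."""
        if self.cr is not None:
            return self.cr
        return cumulative_release(self)


def cumulative_release(curve: ReleaseCurve) -> np.ndarray:
    """Sampling-corrected cumulative percent released at each timepoint.

    ``CR_n = (Ve * sum_{i<n} C_i + Vo * C_n) / m * 100``; the first point
    carries no correction term.
    """
    if curve.conc is None:
        raise ValueError("curve has no measured concentrations")
    c = curve.conc
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return (curve.Ve * prior + curve.Vo * c) / curve.m * 100.0


# ---------------------------------------------------------------------------
# kinetic models


def _zero(t, k0):
    return k0 * t


def _first(t, k1):
    return 100.0 * (1.0 - np.exp(-k1 * t))


def _higuchi(t, kh):
    return kh * np.sqrt(t)


def _kp(t, kkp, n):
    return kkp * np.power(t, n)


def _hixson(t, khc):
    return 100.0 - (100.0 ** (1.0 / 3.0) - khc * t) ** 3


def _init_zero(t, f):
    return [max(float(np.sum(f * t) / np.sum(t * t)), 1e-6)]


def _init_first(t, f):
    frac = np.clip(1.0 - f / 100.0, 1e-9, 1.0)
    return [max(float(np.sum(-np.log(frac) * t) / np.sum(t * t)), 1e-6)]


def _init_higuchi(t, f):
    s = np.sqrt(t)
    return [max(float(np.sum(f * s) / np.sum(s * s)), 1e-6)]


def _init_kp(t, f):
    ok = f > 0
    if ok.sum() < 2:
        return [1.0, 0.5]
    lt, lf = np.log(t[ok]), np.log(f[ok])
    n, logk = np.polyfit(lt, lf, 1)
    return [float(np.exp(logk)), float(np.clip(n, 0.01, 3.0))]


def _init_hixson(t, f):
    cube = 100.0 ** (1.0 / 3.0) - np.cbrt(np.clip(100.0 - f, 0.0, None))
    return [max(float(np.sum(cube * t) / np.sum(t * t)), 1e-9)]


MODELS = {
    "zero_order": {"func": _zero, "params": ("K0",), "init": _init_zero},
    "first_order": {"func": _first, "params": ("K1",), "init": _init_first},
    "higuchi": {"func": _higuchi, "params": ("KH",), "init": _init_higuchi},
    "korsmeyer_peppas": {"func": _kp, "params": ("KKP", "n"), "init": _init_kp},
    "hixson_crowell": {"func": _hixson, "params": ("KHC",), "init": _init_hixson},
}


def information_criteria(ssr: float, sst: float, n: int, p: int):
    """``(R^2, AIC, MSC)`` from residual and total sums of squares.

    ``R^2 = 1 - SSR/SST``; ``AIC = n*ln(SSR) + 2p`` (unit-weight form);
    ``MSC = ln(SST/SSR) - 2p/n``.  A perfect fit (SSR = 0) returns the
    ``-inf``/``+inf`` sentinels for AIC/MSC.
    """
    if n <= p:
        raise ValueError("need n > p")
    if sst <= 0:
        raise ValueError("SST must be positive")
    if ssr < 0:
        raise ValueError("SSR must be non-negative")
    if ssr == 0.0:
        return 1.0, -np.inf, np.inf
    r2 = 1.0 - ssr / sst
    aic = n * np.log(ssr) + 2.0 * p
    msc = np.log(sst / ssr) - 2.0 * p / n
    return r2, aic, msc


def classify_exponent(n: float, tol: float = 1e-9) -> str:
    """Transport-mechanism label for a Korsmeyer-Peppas exponent.

    n < 0.45 quasi-Fickian; n = 0.45 Fickian; 0.45 < n < 0.89
    anomalous (non-Fickian); n = 0.89 case II / zero-order; n > 0.89
    super case II.  Equality is taken within ``tol``.
    """
    if not np.isfinite(n):
        raise ValueError("exponent must be finite")
    if abs(n - 0.45) <= tol:
        return "Fickian diffusion"
    if abs(n - 0.89) <= tol:
        return "case II (zero-order) transport"
    if n < 0.45:
        return "quasi-Fickian diffusion"
    if n < 0.89:
        return "non-Fickian (anomalous) transport"
    return "super case II transport"


@dataclass
class KineticFitResult:
    """One kinetic model fitted to a release curve."""

    model: str
    params: dict
    r2: float
    aic: float
    msc: float
    n_points: int
    n_params: int
    ssr: float
    sst: float
    converged: bool = True
    exponent_class: str | None = None

    def summary(self) -> str:
        pstr = ", ".join(f"{k} = {v:.4g}" for k, v in self.params.items())
        line = (f"{self.model}: {pstr}; R² = {self.r2:.4f}, "
                f"AIC = {self.aic:.2f}, MSC = {self.msc:.4f}")
        if self.exponent_class:
            line += f" [{self.exponent_class}]"
        if not self.converged:
            line += " (NOT CONVERGED: linearized estimate)"
        return line

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "r2": float(self.r2),
            "aic": float(self.aic),
            "msc": float(self.msc),
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "exponent_class": self.exponent_class,
        }


class ReleaseKineticsModel:
    """Nonlinear least-squares fit of one kinetic model to (t, CR) data.

    t = 0 points are dropped (log-linearizations are undefined there and
    CR(0) is 0 by construction).  Points may arrive in any order; they are
    sorted internally.
    """

    def __init__(self, times, cr, model: str = "korsmeyer_peppas"):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
        t = np.asarray(times, dtype=float)
        f = np.asarray(cr, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative timepoints are not allowed")
        keep = t > 0
        order = np.argsort(t[keep], kind="stable")
        self.t = t[keep][order]
        self.f = f[keep][order]
        self.model = model
        spec = MODELS[model]
        if len(self.t) < len(spec["params"]) + 1:
            raise ValueError(
                f"{model} needs at least {len(spec['params']) + 1} points with t > 0"
            )

    def fit(self) -> KineticFitResult:
        spec = MODELS[self.model]
        func, names = spec["func"], spec["params"]
        p = len(names)
        n = len(self.t)
        p0 = spec["init"](self.t, self.f)
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(func, self.t, self.f, p0=p0, maxfev=20000)
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite parameters")
        except (RuntimeError, ValueError):
            popt, converged = np.asarray(p0, dtype=float), False

        resid = self.f - func(self.t, *popt)
        ssr = float(resid @ resid)
        sst = float(np.sum((self.f - self.f.mean()) ** 2))
        if sst <= 0:
            # constant CR: R^2 undefined, report degenerate fit
            result = KineticFitResult(
                self.model, dict(zip(names, popt)), np.nan, np.nan, np.nan,
                n, p, ssr, sst, converged=False,
            )
            return result
        r2, aic, msc = information_criteria(ssr, sst, n, p)
        exp_class = None
        if self.model == "korsmeyer_peppas":
            exp_class = classify_exponent(float(dict(zip(names, popt))["n"]))
        return KineticFitResult(
            self.model, dict(zip(names, map(float, popt))), r2, aic, msc,
            n, p, ssr, sst, converged=converged, exponent_class=exp_class,
        )


def fit_kinetic(model: str, times, cr) -> KineticFitResult:
    """Fit one named kinetic model; see :class:`ReleaseKineticsModel`."""
    return ReleaseKineticsModel(times, cr, model).fit()


def fit_all_models(times, cr) -> list[KineticFitResult]:
    """Fit every registered model to the same data."""
    return [ReleaseKineticsModel(times, cr, m).fit() for m in MODELS]


def select_model(results: list[KineticFitResult]) -> KineticFitResult:
    """Pick the best fit: highest MSC, ties going to fewer parameters.

    Only converged fits compete.  At fixed n, ranking by MSC descending is
    identical to AIC ascending.
    """
    ok = [r for r in results if r.converged and np.isfinite(r.r2)]
    if len(ok) == 0:
        raise ModelSelectionError("no converged kinetic fits to select from")
    best = ok[0]
    for r in ok[1:]:
        both_inf = np.isinf(r.msc) and np.isinf(r.msc) == np.isinf(best.msc) and r.msc == best.msc
        if both_inf or abs(r.msc - best.msc) <= 1e-9:
            if r.n_params < best.n_params:
                best = r
        elif r.msc > best.msc:
            best = r
    return best
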