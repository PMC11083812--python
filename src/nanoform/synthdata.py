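"""Seeded synthetic-data generators mirroring each analysis stage.

Every generator is a pure function of its parameters and an explicit
integer seed (``numpy.random.default_rng``; no global state), and every
zero-noise setting round-trips exactly through the matching analysis stage:

* a design filled from a known coefficient vector with ``sd = 0`` is
  recovered term-for-term by the OLS fit;
* a release curve generated from a kinetic model with ``sigma = 0`` and the
  sampling scheme switched on reproduces its true cumulative percents
  through :func:`nanoform.release.cumulative_release`;
* a plate generated with ``cv = 0`` yields exactly the requested
  percent-of-control levels.

Default noise scales are chosen to resemble replicate scatter typical of
DLS/UV formulation readouts (a few nm on size, a few tenths of a percent
on EE); they are defaults, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioassay import AssayPlate
from .doe import DesignTable
from .release import MODELS, ReleaseCurve
from .rsm import term_columns

__all__ = [
    "SurfaceTruth",
    "gen_rsm_dataset",
    "gen_release_curve",
    "gen_assay_plate",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """A known response surface: coefficients in coded units plus noise SD."""

    coefficients: dict
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def gen_rsm_dataset(
    design: DesignTable, truth: SurfaceTruth, response: str = "Y"
) -> DesignTable:
    """Fill ``design`` with a response drawn from a known surface.

    ``value = sum_t coef_t * x_t + Normal(0, noise_sd)`` per run, with the
    noise stream fixed by ``truth.seed``.  ``noise_sd = 0`` gives the exact
    model values.
    """
    X = term_columns(design.coded, list(truth.coefficients))
    mean = X.to_numpy() @ np.array([truth.coefficients[t] for t in X.columns])
    rng = np.random.default_rng(truth.seed)
    y = mean + rng.normal(0.0, truth.noise_sd, size=len(mean))
    return design.with_response(response, y)


def gen_release_curve(
    model: str,
    params: dict,
    timepoints,
    sigma: float = 0.0,
    seed: int = 0,
    sampling: tuple | None = None,
) -> ReleaseCurve:
    """Generate a release curve from a named kinetic model.

    The true cumulative percents ``CR(t)`` are evaluated from the model,
    clipped at 100 % (with a warning) where the polynomial forms overshoot,
    and Gaussian noise of SD ``sigma`` (percent units) is added.  When
    ``sampling = (Ve, Vo, m)`` is given, the (noisy) percents are
    back-converted to the measured concentrations an experimenter would
    record under the aliquot-and-replace protocol, so that
    :func:`nanoform.release.cumulative_release` returns them exactly.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    spec = MODELS[model]
    names = spec["params"]
    missing = set(names) - set(params)
    if missing:
        raise ValueError(f"missing parameters for {model}: {sorted(missing)}")
    vals = [float(params[k]) for k in names]
    if any(v < 0 for v in vals):
        raise ValueError("rate constants must be non-negative")
    if model == "korsmeyer_peppas" and params["n"] <= 0:
        raise ValueError("Korsmeyer-Peppas exponent n must be positive")

    t = np.asarray(timepoints, dtype=float)
    if np.any(t <= 0):
        raise ValueError("timepoints must be positive")
    cr = spec["func"](t, *vals)
    if np.any(cr > 100.0):
        import warnings

        warnings.warn("generated release exceeds 100%: clipped", stacklevel=2)
        cr = np.minimum(cr, 100.0)

    rng = np.random.default_rng(seed)
    cr = cr + rng.normal(0.0, sigma, size=len(t))
    cr = np.clip(cr, 0.0, 100.0)

    if sampling is None:
        return ReleaseCurve(times=t, cr=cr)

    Ve, Vo, m = sampling
    # invert CR_n = (Ve*sum_{i<n} C_i + Vo*C_n)/m * 100 for the concentrations
    conc = np.empty_like(cr)
    acc = 0.0
    for i, c in enumerate(cr):
        conc[i] = (m * c / 100.0 - Ve * acc) / Vo
        acc += conc[i]
    if np.any(conc < 0):
        # heavy noise can make an implied aliquot negative; floor at zero
        conc = np.maximum(conc, 0.0)
    return ReleaseCurve(times=t, conc=conc, Ve=Ve, Vo=Vo, m=m)


def gen_assay_plate(
    true_levels: dict,
    cv: float = 0.1,
    n: int = 3,
    seed: int = 0,
    stimulated_control: str = "control",
) -> AssayPlate:
    """Generate a plate with lognormal replicate noise around known levels.

    ``true_levels`` maps condition label -> percent-of-control level; the
    stimulated control itself is added at level 100 if absent.  Replicates
    are ``level * LogNormal`` with unit mean and coefficient of variation
    ``cv`` (so the generator is unbiased), scaled so the control mean sits
    at 100 signal units.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 1:
        raise ValueError("need at least one replicate")
    levels = dict(true_levels)
    levels.setdefault(stimulated_control, 100.0)
    rng = np.random.default_rng(seed)
    s = np.sqrt(np.log1p(cv**2))
    rows = []
    for cond, lvl in levels.items():
        noise = (
            np.ones(n)
            if cv == 0
            else np.exp(rng.normal(-(s**2) / 2.0, s, size=n))
        )
        for r, x in enumerate(lvl * noise, start=1):
            rows.append({"condition": cond, "replicate": r, "signal": x})
    data = pd.DataFrame(rows)
    return AssayPlate(data, stimulated_control=stimulated_control)
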