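"""End-to-end pipeline: fit -> reduce -> optimize -> validate, plus the
optional release-kinetics and plate-assay stages.

Each stage is independent: a failure in one is recorded in the report
(``stages[<name>]["status"] = "failed"``) without aborting the others.
Given identical inputs and seeds the JSON report is byte-identical between
runs.
"""

from __future__ import annotations

import traceback

from .bioassay import AssayPlate
from .doe import DesignTable
from .io import PipelineConfig
from .optimize import (
    DesirabilityGoal,
    optimize_desirability,
    percent_error,
    predict_interval,
)
from .release import ReleaseCurve, fit_all_models, select_model
from .rsm import ResponseSurfaceModel, reduce_model

__all__ = ["run_pipeline"]


def _goal_from_config(g, design: DesignTable) -> DesirabilityGoal:
    lo, hi = g.lower, g.upper
    if lo is None or hi is None:
        y = design.response(g.response)
        lo = y.min() if lo is None else lo
        hi = y.max() if hi is None else hi
    return DesirabilityGoal(
        g.response, g.kind, float(lo), float(hi), target=g.target,
        weight=g.weight, importance=g.importance,
        constraint_upper=g.constraint_upper, constraint_lower=g.constraint_lower,
    )


def run_pipeline(
    config: PipelineConfig,
    design: DesignTable,
    release_curves: dict[str, ReleaseCurve] | None = None,
    assay_plates: dict[str, AssayPlate] | None = None,
    observed: dict[str, float] | None = None,
) -> dict:
    """Execute the full analysis and return a JSON-serializable report.

    Parameters
    ----------
    config : PipelineConfig
    design : DesignTable
        Must carry every response named in ``config.responses``.
    release_curves, assay_plates : dict, optional
        Labelled extra inputs for the release / assay stages.
    observed : dict, optional
        Measured responses of a confirmation batch; when given, the
        validation block reports percent errors and 95 % prediction
        intervals at the located optimum.
    """
    report: dict = {"seed": config.seed, "stages": {}}
    fits = {}

    # ---- fit / reduce -------------------------------------------------
    try:
        block = {}
        for resp in config.responses:
            spec = config.terms.get(resp, "auto")
            if spec == "auto":
                fit = reduce_model(design, resp, alpha=config.alpha)
            else:
                fit = ResponseSurfaceModel(design, resp, spec).fit()
            fits[resp] = fit
            block[resp] = fit.to_dict()
        report["stages"]["fit"] = {"status": "ok", "models": block}
    except Exception as exc:  # pragma: no cover - defensive
        report["stages"]["fit"] = {
            "status": "failed", "error": str(exc),
            "traceback": traceback.format_exc(),
        }
        return report

    # ---- optimize -----------------------------------------------------
    opt = None
    if config.goals:
        try:
            goals = [_goal_from_config(g, design) for g in config.goals]
            opt = optimize_desirability(
                [fits[g.response] for g in goals], goals, seed=config.seed
            )
            report["stages"]["optimize"] = {
                "status": "ok",
                "coded": opt.coded.tolist(),
                "actual": opt.actual,
                "predicted": opt.predicted,
                "desirability": opt.desirabilities,
                "overall_desirability": opt.overall,
            }
        except Exception as exc:
            report["stages"]["optimize"] = {"status": "failed", "error": str(exc)}

    # ---- validate -----------------------------------------------------
    if observed and opt is not None:
        try:
            rows = {}
            for resp, obs in observed.items():
                fit = fits[resp]
                pi = predict_interval(fit, opt.coded, level=0.95)
                rows[resp] = {
                    "predicted": pi.point,
                    "observed": obs,
                    "pi_low": pi.lower,
                    "pi_high": pi.upper,
                    "percent_error": percent_error(obs, pi.point),
                }
            report["stages"]["validate"] = {"status": "ok", "responses": rows}
        except Exception as exc:
            report["stages"]["validate"] = {"status": "failed", "error": str(exc)}

    # ---- release kinetics --------------------------------------------
    if release_curves:
        block = {}
        for label, curve in release_curves.items():
            try:
                cr = curve.cumulative()
                results = fit_all_models(curve.times, cr)
                best = select_model(results)
                block[label] = {
                    "status": "ok",
                    "models": [r.to_dict() for r in results],
                    "best": best.to_dict(),
                }
            except Exception as exc:
                block[label] = {"status": "failed", "error": str(exc)}
        report["stages"]["release"] = block

    # ---- assays -------------------------------------------------------
    if assay_plates:
        block = {}
        for label, plate in assay_plates.items():
            try:
                block[label] = {
                    "status": "ok",
                    "conditions": [s.to_dict() for s in plate.summarize()],
                }
            except Exception as exc:
                block[label] = {"status": "failed", "error": str(exc)}
        report["stages"]["assay"] = block

    return report
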