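"""Packaged study data: the CBD-SLN Box-Behnken formulation dataset.

The packaged design table is the published 15-run Box-Behnken matrix for a
cannabidiol solid-lipid-nanoparticle formulation: factors glyceryl
monostearate (GMS, 1.5-2.5 g), polysorbate 80 (P80, 0.6-1.0 g) and
methanolic CBD (10-20 mg); responses particle size Y1 (nm), polydispersity
index Y2, encapsulation efficiency Y3 (%) and drug loading Y4 (%).  Runs
F13-F15 are the replicated center points.  Response values are the
published replicate means.

Also exposed are the published reduced term sets per response, the
optimization goals, and the validation table (predicted vs observed at the
confirmed optimum) used by the worked examples.
"""

from __future__ import annotations

from importlib.resources import files

from .doe import DesignTable
from .io import read_design_csv, read_factors
from .optimize import DesirabilityGoal

__all__ = [
    "load_cbd_sln_factors",
    "load_cbd_sln_design",
    "cbd_sln_goals",
    "CBD_SLN_TERMS",
    "CBD_SLN_VALIDATION",
    "CBD_SLN_OPTIMUM_CODED",
    "RESPONSE_LABELS",
]

RESPONSE_LABELS = {
    "Y1": "particle size (nm)",
    "Y2": "PDI",
    "Y3": "EE (%)",
    "Y4": "DL (%)",
}

#: published reduced term sets per response (model hierarchy preserved)
CBD_SLN_TERMS = {
    "Y1": ("1", "A", "B", "C", "AB", "BC", "A^2", "B^2", "C^2"),
    "Y2": ("1", "A", "B", "C", "AB", "A^2", "B^2", "C^2"),
    "Y3": ("1", "A", "B", "C"),
    "Y4": ("1", "A", "B", "C", "AC", "BC", "A^2"),
}

#: confirmed optimum in coded units (GMS 1.60 g, P80 0.62 g, CBD 20 mg)
CBD_SLN_OPTIMUM_CODED = (-0.8, -0.9, 1.0)

#: published validation table at the optimum: predicted vs observed per response
CBD_SLN_VALIDATION = {
    "Y1": {"predicted": 119.36, "observed": 123.40},
    "Y2": {"predicted": 0.1910, "observed": 0.2099},
    "Y3": {"predicted": 95.33, "observed": 95.16},
    "Y4": {"predicted": 2.35, "observed": 2.36},
}


def _data(name: str):
    return files("nanoform.data").joinpath(name)


def load_cbd_sln_factors():
    """The three formulation factors with their coding anchors."""
    return read_factors(_data("factors.yaml"))


def load_cbd_sln_design() -> DesignTable:
    """The 15-run design table with all four measured responses."""
    return read_design_csv(_data("bbd_design.csv"), load_cbd_sln_factors())


def cbd_sln_goals(design: DesignTable | None = None) -> list[DesirabilityGoal]:
    """The study's optimization goals with observed-range anchors.

    Size and PDI are minimized (size additionally capped at 200 nm as a
    hard constraint), EE and DL maximized; anchors default to each
    response's observed range, the conventional choice when no explicit
    anchors are given.
    """
    design = design if design is not None else load_cbd_sln_design()
    rng = {r: (design.response(r).min(), design.response(r).max())
           for r in ("Y1", "Y2", "Y3", "Y4")}
    return [
        DesirabilityGoal("Y1", "minimize", *rng["Y1"], constraint_upper=200.0),
        DesirabilityGoal("Y2", "minimize", *rng["Y2"]),
        DesirabilityGoal("Y3", "maximize", *rng["Y3"]),
        DesirabilityGoal("Y4", "maximize", *rng["Y4"]),
    ]
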