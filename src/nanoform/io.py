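"""File formats and validated pipeline configuration.

CSV schemas
-----------
design
    ``run,A,B,C[,Y1,Y2,Y3,Y4]`` in actual units, with a sibling YAML/JSON
    factor file declaring ``name/low/high/units`` per factor.  The writer
    additionally emits coded columns (``coded_<name>``).
release
    ``time_h,conc_mg_per_ml`` or ``time_h,cr_percent`` — auto-detected from
    the header.
assay
    long format ``condition,replicate,signal``.

Configuration is a YAML/JSON document validated by pydantic with unknown
keys rejected, so typos fail loudly with a precise location.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .doe import DesignTable, Factor
from .release import ReleaseCurve

__all__ = [
    "read_factors",
    "write_factors",
    "read_design_csv",
    "write_design_csv",
    "read_release_csv",
    "write_release_csv",
    "read_assay_csv",
    "PipelineConfig",
    "GoalConfig",
    "VesselConfig",
    "ThresholdConfig",
    "load_config",
    "write_json_report",
]


# ---------------------------------------------------------------------------
# factors


def read_factors(path) -> tuple[Factor, ...]:
    """Load factor definitions from a YAML or JSON file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    factors = doc["factors"] if isinstance(doc, dict) else doc
    return tuple(
        Factor(f["name"], float(f["low"]), float(f["high"]), f.get("units", ""))
        for f in factors
    )


def write_factors(factors, path) -> None:
    doc = {
        "factors": [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in factors
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# design tables


def read_design_csv(path, factors) -> DesignTable:
    """Read a design CSV (actual units) against known factor definitions."""
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: design file has no runs")
    factors = tuple(factors)
    missing = [f.name for f in factors if f.name not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing factor columns {missing}")
    index = (
        frame["run"].astype(str).tolist()
        if "run" in frame.columns
        else [f"F{i+1}" for i in range(len(frame))]
    )
    coded = pd.DataFrame(
        {f.name: f.to_coded(frame[f.name].to_numpy(dtype=float)) for f in factors},
        index=index,
    )
    resp_cols = [
        c
        for c in frame.columns
        if c not in {"run", *[f.name for f in factors]}
        and not c.startswith("coded_")
    ]
    responses = frame[resp_cols].astype(float)
    responses.index = index
    return DesignTable(factors, coded, responses=responses)


def write_design_csv(design: DesignTable, path) -> None:
    """Write actual + coded settings and responses; 12-significant-digit text."""
    actual = design.actual
    coded = design.coded.add_prefix("coded_")
    out = pd.concat([actual, coded, design.responses], axis=1)
    out.insert(0, "run", out.index)
    out.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# release curves


def read_release_csv(path, Ve: float = 1.0, Vo: float = 200.0, m: float = 1.0) -> ReleaseCurve:
    """Read a release time course; concentration vs percent auto-detected."""
    frame = pd.read_csv(path)
    if "time_h" not in frame.columns:
        raise ValueError(f"{path}: expected a 'time_h' column")
    t = frame["time_h"].to_numpy(dtype=float)
    if "conc_mg_per_ml" in frame.columns:
        return ReleaseCurve(
            times=t, conc=frame["conc_mg_per_ml"].to_numpy(dtype=float),
            Ve=Ve, Vo=Vo, m=m,
        )
    if "cr_percent" in frame.columns:
        return ReleaseCurve(
            times=t, cr=frame["cr_percent"].to_numpy(dtype=float),
            Ve=Ve, Vo=Vo, m=m,
        )
    raise ValueError(f"{path}: need 'conc_mg_per_ml' or 'cr_percent'")


def write_release_csv(curve: ReleaseCurve, path) -> None:
    if curve.conc is not None:
        frame = pd.DataFrame({"time_h": curve.times, "conc_mg_per_ml": curve.conc})
    else:
        frame = pd.DataFrame({"time_h": curve.times, "cr_percent": curve.cr})
    frame.to_csv(path, index=False, float_format="%.12g")


def read_assay_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"condition", "replicate", "signal"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: assay CSV needs columns {sorted(required)}")
    return frame


# ---------------------------------------------------------------------------
# configuration


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    low: float
    high: float
    units: str = ""

    def build(self) -> Factor:
        return Factor(self.name, self.low, self.high, self.units)


class GoalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    response: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0
    constraint_upper: float | None = None
    constraint_lower: float | None = None

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("minimize", "maximize", "target", "in_range"):
            raise ValueError(f"unknown goal kind {v!r}")
        return v


class VesselConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Ve: float = 1.0
    Vo: float = 200.0
    m: float = 1.0


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pdi_max: float = 0.3
    pdi_aggregation: float = 0.7
    zeta_min_abs: float = 30.0


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    factors: list[FactorConfig]
    responses: list[str] = Field(default_factory=lambda: ["Y1", "Y2", "Y3", "Y4"])
    terms: dict[str, list[str] | str] = Field(default_factory=dict)  # or "auto"
    alpha: float = 0.05
    goals: list[GoalConfig] = Field(default_factory=list)
    vessel: VesselConfig = VesselConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    seed: int = 0
    output_dir: str = "."

    def build_factors(self) -> tuple[Factor, ...]:
        return tuple(f.build() for f in self.factors)


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(doc)


def write_json_report(report: dict, path) -> None:
    """Deterministic, full-precision JSON (sorted keys, newline-terminated)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=default) + "\n"
    )
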