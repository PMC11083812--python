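"""Encapsulation-efficiency and drug-loading arithmetic plus colloidal
quality checks.

With ``Wt`` the drug mass dosed into the formulation, ``Ws`` the free drug
recovered in the supernatant after ultracentrifugation, and ``Wnp`` the
lyophilized nanoparticle mass (all in the same mass unit):

.. math::

    EE\\,(\\%) = \\frac{W_t - W_s}{W_t} \\times 100, \\qquad
    DL\\,(\\%) = \\frac{W_t - W_s}{W_{np}} \\times 100

so ``EE * Wt == DL * Wnp`` identically.  Colloidal acceptance follows the
conventional thresholds for lipid carriers: PDI <= 0.3 acceptable, PDI >
0.7 prone to aggregation (ISO guidance), and |zeta| >= 30 mV for an
electrostatically stabilized dispersion.  Thresholds are parameters, not
constants, so laboratories with different acceptance rules can override
them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FormulationMeasurement",
    "ColloidalReport",
    "Thresholds",
    "encapsulation_efficiency",
    "drug_loading",
    "colloidal_checks",
    "InvalidMeasurementError",
]


class InvalidMeasurementError(ValueError):
    """Raised for physically impossible mass measurements (e.g. Ws > Wt)."""


@dataclass(frozen=True)
class Thresholds:
    """Colloidal acceptance thresholds (all comparisons inclusive)."""

    pdi_max: float = 0.3
    pdi_aggregation: float = 0.7
    zeta_min_abs: float = 30.0


@dataclass(frozen=True)
class FormulationMeasurement:
    """One formulation batch: masses plus colloidal readouts.

    Masses share one unit (mg by convention); ``size`` in nm, ``zeta`` in mV.
    """

    Wt: float
    Ws: float
    Wnp: float | None = None
    size: float | None = None
    pdi: float | None = None
    zeta: float | None = None


@dataclass(frozen=True)
class ColloidalReport:
    """Pass/fail flags from :func:`colloidal_checks`."""

    pdi_ok: bool | None
    zeta_ok: bool | None
    aggregation_warning: bool
    thresholds: Thresholds

    @property
    def all_ok(self) -> bool:
        checks = [c for c in (self.pdi_ok, self.zeta_ok) if c is not None]
        return bool(checks) and all(checks) and not self.aggregation_warning

    def to_dict(self) -> dict:
        return {
            "pdi_ok": self.pdi_ok,
            "zeta_ok": self.zeta_ok,
            "aggregation_warning": self.aggregation_warning,
            "all_ok": self.all_ok,
        }


def encapsulation_efficiency(Wt: float, Ws: float) -> float:
    """Percent of dosed drug retained in the particles."""
    if Wt <= 0:
        raise ValueError("initial drug mass Wt must be positive")
    if Ws < 0:
        raise InvalidMeasurementError("free drug mass Ws cannot be negative")
    if Ws > Wt:
        raise InvalidMeasurementError(
            f"free drug ({Ws}) exceeds dosed drug ({Wt})"
        )
    return (Wt - Ws) / Wt * 100.0


def drug_loading(Wt: float, Ws: float, Wnp: float) -> float:
    """Encapsulated drug mass as a percent of nanoparticle mass."""
    if Wnp is None or Wnp <= 0:
        raise ValueError("nanoparticle mass Wnp must be positive")
    if Ws < 0:
        raise InvalidMeasurementError("free drug mass Ws cannot be negative")
    if Ws > Wt:
        raise InvalidMeasurementError(
            f"free drug ({Ws}) exceeds dosed drug ({Wt})"
        )
    return (Wt - Ws) / Wnp * 100.0


def colloidal_checks(
    m: FormulationMeasurement, thresholds: Thresholds = Thresholds()
) -> ColloidalReport:
    """Evaluate PDI and zeta-potential acceptance for one batch.

    Missing readouts yield ``None`` flags rather than failures.
    """
    pdi_ok = None if m.pdi is None else m.pdi <= thresholds.pdi_max
    zeta_ok = None if m.zeta is None else abs(m.zeta) >= thresholds.zeta_min_abs
    aggregation = m.pdi is not None and m.pdi > thresholds.pdi_aggregation
    return ColloidalReport(pdi_ok, zeta_ok, aggregation, thresholds)
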