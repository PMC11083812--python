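"""Plate-assay normalization: percent-of-control levels, percent
inhibition and fold potency.

Raw plate-reader signals (absorbance or fluorescence, arbitrary units) are
normalized to the mean of the stimulated, untreated control so that a
treatment's readout becomes a *level* in percent of control.  Inhibition is
the complement, ``100 - level``, and the relative potency of two treatments
is the ratio of their residual levels: a treatment leaving 62 % of control
versus a reference leaving 77 % is ``77/62 = 1.24``, i.e. about 1.2-fold
more potent.  (The alternative convention — ratio of inhibitions — gives a
different number and is deliberately not used here; residual-level ratio is
the definition consistent with how fold-potency figures are commonly
quoted for this kind of readout.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayPlate",
    "ConditionSummary",
    "percent_of_control",
    "percent_inhibition",
    "fold_potency",
    "welch_t",
    "NormalizationError",
]


class NormalizationError(ValueError):
    """Raised when the control mean is non-positive."""


def percent_of_control(signal: float, control_mean: float) -> float:
    """Signal as a percent of the (stimulated) control mean."""
    if control_mean <= 0:
        raise NormalizationError("control mean must be positive")
    return signal / control_mean * 100.0


def percent_inhibition(level_percent: float) -> float:
    """Inhibition implied by a percent-of-control level: ``100 - level``."""
    return 100.0 - level_percent


def fold_potency(level_reference: float, level_test: float) -> float:
    """Ratio of residual levels, reference over test.

    A value above 1 means the test treatment suppresses the readout more
    strongly than the reference.  Antisymmetric under swapping arguments:
    ``fold_potency(a, b) * fold_potency(b, a) == 1``.
    """
    if level_test == 0:
        raise ZeroDivisionError("fold potency undefined for a zero test level")
    return level_reference / level_test


def welch_t(a, b) -> tuple[float, float]:
    """Two-group Welch t-test (convenience wrapper): returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate-aggregated readout for one condition."""

    condition: str
    n: int
    level_mean: float
    level_sd: float | None
    inhibition: float

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "level_percent": self.level_mean,
            "level_sd": self.level_sd,
            "inhibition_percent": self.inhibition,
        }


@dataclass
class AssayPlate:
    """Raw signals for one plate, long format, with control designations.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``condition``, ``replicate``, ``signal``.
    stimulated_control : str
        Condition label whose mean signal defines 100 %.
    untreated_control : str, optional
        Unstimulated baseline (reported but not used for normalization).
    """

    data: pd.DataFrame
    stimulated_control: str
    untreated_control: str | None = None
    _groups: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        required = {"condition", "replicate", "signal"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"assay data needs columns {sorted(required)}")
        if self.stimulated_control not in set(self.data["condition"]):
            raise ValueError(
                f"stimulated control {self.stimulated_control!r} not on plate"
            )
        self._groups = {
            c: g["signal"].to_numpy(dtype=float)
            for c, g in self.data.groupby("condition", sort=False)
        }
        if self.control_mean <= 0:
            raise NormalizationError("stimulated-control mean must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(self._groups)

    @property
    def control_mean(self) -> float:
        return float(self._groups[self.stimulated_control].mean())

    def summarize(self) -> list[ConditionSummary]:
        """Mean +/- SD percent-of-control level and inhibition per condition."""
        ref = self.control_mean
        out = []
        for cond, sig in self._groups.items():
            levels = sig / ref * 100.0
            sd = float(levels.std(ddof=1)) if len(levels) > 1 else None
            mean = float(levels.mean())
            out.append(
                ConditionSummary(cond, len(levels), mean, sd,
                                 percent_inhibition(mean))
            )
        return out

    def level(self, condition: str) -> float:
        """Mean percent-of-control level for one condition."""
        return float(self._groups[condition].mean() / self.control_mean * 100.0)

    def fold_potency(self, reference: str, test: str) -> float:
        """Fold potency of ``test`` relative to ``reference`` (level ratio)."""
        return fold_potency(self.level(reference), self.level(test))
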