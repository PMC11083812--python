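"""Box-Behnken designs and factor coding.

A three-factor Box-Behnken design (BBD) places runs at the midpoints of the
edges of the factor cube -- every factor pair at the four (+/-1, +/-1)
combinations while the third factor sits at its center -- plus replicated
center points.  The 12 edge runs make all linear and pairwise-interaction
columns mutually orthogonal, which is what lets a second-order polynomial be
estimated efficiently from only ``12 + c`` runs.

Factor levels are handled in *coded units*: the low actual level maps to -1,
the midpoint to 0 and the high level to +1.  All model fitting downstream
happens on the coded scale; :meth:`Factor.to_actual` converts back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignTable",
    "bbd_design",
    "DegenerateFactorError",
    "UnsupportedDesignError",
]

#: canonical response labels used throughout the package
RESPONSE_NAMES = ("Y1", "Y2", "Y3", "Y4")


class DegenerateFactorError(ValueError):
    """Raised when a factor has zero half-range (low == high)."""


class UnsupportedDesignError(ValueError):
    """Raised when a design other than the supported 3-factor BBD is requested."""


@dataclass(frozen=True)
class Factor:
    """A continuous experimental factor with two-level coding anchors.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"A"`` or ``"GMS"``.
    low, high : float
        Actual values at coded -1 and +1.  ``low < high`` is required.
    units : str
        Free-text units (``"g"``, ``"mg"``, ...), used only for display.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"factor {self.name!r}: levels must be finite")
        if self.high == self.low:
            raise DegenerateFactorError(
                f"factor {self.name!r}: low == high == {self.low} (zero half-range)"
            )
        if self.low > self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def to_coded(self, actual: float) -> float:
        """Map an actual value onto the coded scale (-1 at low, +1 at high).

        Extrapolation beyond +/-1 is allowed and returned as-is.
        """
        return (np.asarray(actual, dtype=float) - self.center) / self.half_range

    def to_actual(self, coded: float) -> float:
        """Inverse of :meth:`to_coded`."""
        return self.center + np.asarray(coded, dtype=float) * self.half_range


# coded (factor_i, factor_j) combinations within one BBD edge block,
# in the row order the design is conventionally printed
_EDGE_PATTERN = ((-1, -1), (+1, -1), (-1, +1), (+1, +1))


@dataclass
class DesignTable:
    """A design matrix with coded and actual settings and optional responses.

    Attributes
    ----------
    factors : tuple of Factor
        Ordered factors; column order of ``coded``/``actual``.
    coded : pandas.DataFrame
        Runs x factors, entries in coded units; index holds run ids.
    responses : pandas.DataFrame
        Runs x response columns (may be empty).
    is_center : pandas.Series of bool
        Marks replicated center runs.
    """

    factors: tuple[Factor, ...]
    coded: pd.DataFrame
    responses: pd.DataFrame = field(default_factory=pd.DataFrame)
    is_center: pd.Series | None = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        names = [f.name for f in self.factors]
        if list(self.coded.columns) != names:
            raise ValueError("coded columns must match factor names in order")
        if self.is_center is None:
            self.is_center = (self.coded == 0).all(axis=1)
        if self.responses.empty:
            self.responses = pd.DataFrame(index=self.coded.index)

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def actual(self) -> pd.DataFrame:
        """Factor settings in actual units."""
        out = {}
        for f in self.factors:
            out[f.name] = f.to_actual(self.coded[f.name].to_numpy())
        return pd.DataFrame(out, index=self.coded.index)

    def with_response(self, name: str, values) -> "DesignTable":
        """Return a copy with a response column set."""
        resp = self.responses.copy()
        resp[name] = np.asarray(values, dtype=float)
        return DesignTable(self.factors, self.coded.copy(), resp, self.is_center.copy())

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses.columns:
            raise KeyError(f"response {name!r} not present in design table")
        y = self.responses[name].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"response {name!r} has missing values")
        return y

    def to_frame(self) -> pd.DataFrame:
        """Coded + actual settings + responses in one table (for reports)."""
        coded = self.coded.add_prefix("coded_")
        return pd.concat([self.actual, coded, self.responses], axis=1)


def bbd_design(factors, n_center: int = 3) -> DesignTable:
    """Generate a three-factor Box-Behnken design.

    The 12 edge-midpoint runs come first, grouped by factor pair in the
    order (1,2), (1,3), (2,3) with the remaining factor at 0, each block
    enumerated (-,-), (+,-), (-,+), (+,+); the ``n_center`` all-zero
    replicates are appended last.  Ordering is deterministic.

    Parameters
    ----------
    factors : sequence of 3 Factor
    n_center : int
        Number of replicated center points (>= 1).

    Returns
    -------
    DesignTable
        ``12 + n_center`` runs with ids ``F1..F{12+c}``; center runs are
        flagged in ``is_center``.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"Box-Behnken generator supports exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    rows = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for a, b in _EDGE_PATTERN:
            row = [0, 0, 0]
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend([[0, 0, 0]] * n_center)

    index = [f"F{k + 1}" for k in range(len(rows))]
    coded = pd.DataFrame(rows, columns=[f.name for f in factors], index=index, dtype=float)
    is_center = pd.Series([False] * 12 + [True] * n_center, index=index)
    return DesignTable(factors, coded, is_center=is_center)
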