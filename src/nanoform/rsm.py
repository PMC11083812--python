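"""Quadratic response-surface models fit by OLS in coded units.

The model for a response :math:`y` over three coded factors is the full
second-order polynomial

.. math::

    y = b_0 + b_A A + b_B B + b_C C + b_{AB} AB + b_{AC} AC + b_{BC} BC
        + b_{AA} A^2 + b_{BB} B^2 + b_{CC} C^2 + \\varepsilon

or any subset of those terms.  Fitting happens on the coded (-1..+1) scale,
so coefficient magnitudes are directly comparable contrasts.  The ANOVA
table uses partial (type-III) sums of squares, and -- because BBD linear and
interaction columns are orthogonal -- these coincide with sequential sums of
squares for those terms.  Replicated center points supply pure error, which
splits the residual into lack-of-fit and replicate noise.

Model reduction follows the usual backward-elimination recipe: starting from
the full quadratic, repeatedly drop the least significant removable term and
refit until everything remaining is significant at ``alpha`` or protected by
model hierarchy (a retained interaction or square keeps its parent main
effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doe import DesignTable

__all__ = [
    "TERM_UNIVERSE",
    "ResponseSurfaceModel",
    "RSMResults",
    "fit_rsm",
    "reduce_model",
    "pure_error",
    "predicted_r2",
    "term_columns",
    "SingularFitError",
]

#: all candidate terms of the 3-factor quadratic, in canonical order
TERM_UNIVERSE = ("1", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")

#: hierarchy: higher-order term -> the main effects it protects
_PARENTS = {
    "AB": ("A", "B"),
    "AC": ("A", "C"),
    "BC": ("B", "C"),
    "A^2": ("A",),
    "B^2": ("B",),
    "C^2": ("C",),
}

_LETTERS = ("A", "B", "C")


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the model matrix is rank deficient."""


def _canonical_terms(terms) -> tuple[str, ...]:
    terms = set(terms) | {"1"}
    unknown = terms - set(TERM_UNIVERSE)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    return tuple(t for t in TERM_UNIVERSE if t in terms)


def term_columns(coded: pd.DataFrame, terms) -> pd.DataFrame:
    """Build the model-matrix columns for ``terms`` from coded settings.

    Factors are addressed positionally: the first coded column is A, the
    second B, the third C, regardless of how the factors are named.
    """
    terms = _canonical_terms(terms)
    base = {letter: coded.iloc[:, k].to_numpy(dtype=float) for k, letter in enumerate(_LETTERS)}
    cols = {}
    for t in terms:
        if t == "1":
            cols[t] = np.ones(len(coded))
        elif t in _LETTERS:
            cols[t] = base[t]
        elif t.endswith("^2"):
            cols[t] = base[t[0]] ** 2
        else:
            cols[t] = base[t[0]] * base[t[1]]
    return pd.DataFrame(cols, index=coded.index)


def pure_error(design: DesignTable, response: str) -> tuple[float, int]:
    """Pure-error sum of squares and df from replicated settings.

    Runs sharing identical coded settings form replicate groups;
    ``SS = sum over groups of sum((y - group mean)^2)`` and
    ``df = sum(group size - 1)``.  With no replicate group of size >= 2 a
    warning is emitted and ``(0.0, 0)`` returned.
    """
    y = design.response(response)
    groups = design.coded.groupby(list(design.coded.columns), sort=False).indices
    ss, df = 0.0, 0
    for idx in groups.values():
        if len(idx) >= 2:
            yi = y[idx]
            ss += float(np.sum((yi - yi.mean()) ** 2))
            df += len(idx) - 1
    if df == 0:
        warnings.warn("no replicate groups: pure error is zero with 0 df", stacklevel=2)
    return ss, df


@dataclass
class RSMResults:
    """Results of one response-surface OLS fit.

    Carries the coefficient vector, the partial-SS ANOVA table, the
    residual / lack-of-fit / pure-error partition and the usual RSM
    diagnostics (R^2, adjusted and predicted R^2, adequate precision).
    """

    response: str
    terms: tuple[str, ...]
    params: pd.Series
    anova: pd.DataFrame
    ss_total: float
    ss_model: float
    ss_resid: float
    ss_lack_of_fit: float
    ss_pure_error: float
    df_model: int
    df_resid: int
    df_lack_of_fit: int
    df_pure_error: int
    sigma2: float
    rsquared: float
    rsquared_adj: float
    rsquared_pred: float
    press: float
    adeq_precision: float
    hat: np.ndarray
    resid: np.ndarray
    fittedvalues: np.ndarray
    design: DesignTable
    elimination_trace: list = field(default_factory=list)

    # -- prediction -----------------------------------------------------
    def predict(self, coded_points) -> np.ndarray:
        """Evaluate the fitted polynomial at coded points (n x 3 or length-3)."""
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        frame = pd.DataFrame(pts, columns=self.design.factor_names)
        X = term_columns(frame, self.terms).to_numpy()
        return X @ self.params.to_numpy()

    def leverage(self, coded_point) -> float:
        """x'(X'X)^{-1}x at one coded point."""
        frame = pd.DataFrame([np.asarray(coded_point, dtype=float)],
                             columns=self.design.factor_names)
        x = term_columns(frame, self.terms).to_numpy()[0]
        X = term_columns(self.design.coded, self.terms).to_numpy()
        xtx_inv = np.linalg.inv(X.T @ X)
        return float(x @ xtx_inv @ x)

    # -- presentation ---------------------------------------------------
    def equation(self, ndigits: int = 4) -> str:
        """The fitted polynomial written out, e.g. ``+1.36 - 0.3425A + ...``."""
        parts = []
        for t, b in self.params.items():
            coef = round(float(b), ndigits)
            sign = "-" if coef < 0 else "+"
            label = "" if t == "1" else t.replace("^2", "²")
            parts.append(f"{sign} {abs(coef):g}{label}")
        return " ".join(parts).lstrip("+ ").strip()

    def summary(self) -> str:
        """Plain-text summary: equation, ANOVA table and fit statistics."""
        lines = [
            f"Response surface fit: {self.response}",
            f"  {self.response} = {self.equation()}",
            "",
            self.anova.to_string(float_format=lambda v: _fmt(v)),
            "",
            f"R-squared            {self.rsquared:8.4f}",
            f"Adjusted R-squared   {self.rsquared_adj:8.4f}",
            f"Predicted R-squared  {self.rsquared_pred:8.4f}",
            f"Adequate precision   {self.adeq_precision:8.2f}",
        ]
        if self.elimination_trace:
            dropped = ", ".join(step["dropped"] for step in self.elimination_trace)
            lines.append(f"Backward elimination dropped: {dropped}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable report (full precision)."""
        return {
            "response": self.response,
            "terms": list(self.terms),
            "coefficients": {t: float(v) for t, v in self.params.items()},
            "anova": self.anova.reset_index().to_dict(orient="records"),
            "r_squared": self.rsquared,
            "r_squared_adj": self.rsquared_adj,
            "r_squared_pred": self.rsquared_pred,
            "adequate_precision": self.adeq_precision,
            "residual_ms": self.sigma2,
            "elimination_trace": self.elimination_trace,
        }


def _fmt(v: float) -> str:
    """Mirror the usual DoE-report convention for tiny p-values."""
    if np.isnan(v):
        return "     nan"
    if 0 < v < 1e-4:
        return " <0.0001"
    return f"{v:8.4f}"


class ResponseSurfaceModel:
    """OLS response-surface model over a :class:`~nanoform.doe.DesignTable`.

    Parameters
    ----------
    design : DesignTable
        Must carry the named response.
    response : str
        Response column to model.
    terms : iterable of str, optional
        Subset of :data:`TERM_UNIVERSE`; the intercept is always included.
        Defaults to the full quadratic.
    """

    def __init__(self, design: DesignTable, response: str, terms=None):
        self.design = design
        self.response = response
        self.terms = _canonical_terms(terms if terms is not None else TERM_UNIVERSE)
        self.y = design.response(response)
        if design.n_runs < len(self.terms):
            raise ValueError(
                f"{design.n_runs} runs cannot identify {len(self.terms)} terms"
            )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, factors, response: str, terms=None):
        """Build from a plain table of *actual* factor settings + responses."""
        factors = tuple(factors)
        coded = pd.DataFrame(
            {f.name: f.to_coded(frame[f.name].to_numpy(dtype=float)) for f in factors},
            index=frame.index,
        )
        resp = frame[[response]].astype(float)
        design = DesignTable(factors, coded, responses=resp)
        return cls(design, response, terms)

    # ------------------------------------------------------------------
    def _matrix(self, terms=None) -> np.ndarray:
        return term_columns(self.design.coded, terms or self.terms).to_numpy()

    def _check_rank(self, X: np.ndarray) -> None:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # greedy scan: terms whose column lies in the span of earlier ones
            bad = []
            for j in range(1, X.shape[1]):
                sub = X[:, : j + 1]
                if np.linalg.matrix_rank(sub) < j + 1:
                    bad.append(self.terms[j])
            raise SingularFitError(f"collinear terms: {bad}")

    def fit(self) -> RSMResults:
        """Fit by ordinary least squares and assemble the ANOVA table."""
        X = self._matrix()
        self._check_rank(X)
        y = self.y
        n, p = X.shape

        ols = sm.OLS(y, X).fit()
        beta = ols.params
        resid = ols.resid
        fitted = ols.fittedvalues
        hat = ols.get_influence().hat_matrix_diag

        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_resid = float(resid @ resid)
        ss_model = ss_total - ss_resid
        df_model, df_resid = p - 1, n - p
        sigma2 = ss_resid / df_resid if df_resid > 0 else np.nan

        degenerate = ss_total <= 1e-300
        if degenerate:
            warnings.warn(
                f"response {self.response!r} is constant: ANOVA F undefined",
                stacklevel=2,
            )

        # partial (type-III) SS: extra SSR from deleting one term at a time
        rows = []
        msr = ss_model / df_model if df_model > 0 else np.nan
        f_model = msr / sigma2 if sigma2 and not degenerate else np.nan
        p_model = float(stats.f.sf(f_model, df_model, df_resid)) if np.isfinite(f_model) else np.nan
        rows.append(("Model", ss_model, df_model, msr, f_model, p_model))
        for t in self.terms:
            if t == "1":
                continue
            reduced = [u for u in self.terms if u != t]
            Xr = term_columns(self.design.coded, reduced).to_numpy()
            br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
            ssr_red = float(np.sum((y - Xr @ br) ** 2))
            ss_t = ssr_red - ss_resid
            f_t = (ss_t / 1.0) / sigma2 if sigma2 and not degenerate else np.nan
            p_t = float(stats.f.sf(f_t, 1, df_resid)) if np.isfinite(f_t) else np.nan
            rows.append((t, ss_t, 1, ss_t, f_t, p_t))

        ss_pe, df_pe = 0.0, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ss_pe, df_pe = pure_error(self.design, self.response)
        ss_lof = max(ss_resid - ss_pe, 0.0)
        df_lof = df_resid - df_pe
        if df_pe > 0 and df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof = p_lof = np.nan
        rows.append(("Residual", ss_resid, df_resid,
                     sigma2, np.nan, np.nan))
        rows.append(("Lack of fit", ss_lof, df_lof,
                     ss_lof / df_lof if df_lof > 0 else np.nan, f_lof, p_lof))
        rows.append(("Pure error", ss_pe, df_pe,
                     ss_pe / df_pe if df_pe > 0 else np.nan, np.nan, np.nan))
        rows.append(("Total (corr.)", ss_total, n - 1, np.nan, np.nan, np.nan))
        anova = pd.DataFrame(
            rows, columns=["source", "SS", "df", "MS", "F", "p"]
        ).set_index("source")

        if degenerate:
            r2 = adj = pred = np.nan
            press = np.nan
        else:
            r2 = 1.0 - ss_resid / ss_total
            adj = 1.0 - (ss_resid / df_resid) / (ss_total / (n - 1)) if df_resid else np.nan
            if np.any(hat >= 1.0 - 1e-12):
                press = pred = np.nan
            else:
                press = float(np.sum((resid / (1.0 - hat)) ** 2))
                pred = 1.0 - press / ss_total

        span = float(fitted.max() - fitted.min())
        if np.isfinite(sigma2) and sigma2 > 0:
            adeq = span / np.sqrt(p * sigma2 / n)
        elif np.isfinite(sigma2):
            adeq = np.inf
        else:
            adeq = np.nan

        return RSMResults(
            response=self.response,
            terms=self.terms,
            params=pd.Series(beta, index=list(self.terms)),
            anova=anova,
            ss_total=ss_total,
            ss_model=ss_model,
            ss_resid=ss_resid,
            ss_lack_of_fit=ss_lof,
            ss_pure_error=ss_pe,
            df_model=df_model,
            df_resid=df_resid,
            df_lack_of_fit=df_lof,
            df_pure_error=df_pe,
            sigma2=sigma2,
            rsquared=r2,
            rsquared_adj=adj,
            rsquared_pred=pred,
            press=press,
            adeq_precision=adeq,
            hat=np.asarray(hat),
            resid=np.asarray(resid),
            fittedvalues=np.asarray(fitted),
            design=self.design,
        )


def fit_rsm(design: DesignTable, response: str, terms=None) -> RSMResults:
    """Convenience wrapper: ``ResponseSurfaceModel(design, response, terms).fit()``."""
    return ResponseSurfaceModel(design, response, terms).fit()


def predicted_r2(fit: RSMResults) -> float:
    """PRESS-based predicted R^2, ``1 - PRESS/SS_total`` (may be negative)."""
    if np.any(fit.hat >= 1.0 - 1e-12):
        raise ZeroDivisionError("a hat diagonal equals 1: leave-one-out undefined")
    press = float(np.sum((fit.resid / (1.0 - fit.hat)) ** 2))
    return 1.0 - press / fit.ss_total


def _is_protected(term: str, terms) -> bool:
    if term == "1":
        return True
    for higher, mains in _PARENTS.items():
        if higher in terms and term in mains:
            return True
    return False


def reduce_model(
    design: DesignTable,
    response: str,
    alpha: float = 0.05,
    hierarchy: bool = True,
    start_terms=None,
) -> RSMResults:
    """Backward-eliminate the full quadratic down to significant terms.

    At each step the removable term (not the intercept, not
    hierarchy-protected when ``hierarchy``) with the largest partial-F
    p-value above ``alpha`` is dropped and the model refit.  Stops when all
    remaining terms are significant or protected.  The final
    :class:`RSMResults` carries the elimination trace.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    terms = list(_canonical_terms(start_terms if start_terms is not None else TERM_UNIVERSE))
    trace = []
    while True:
        fit = ResponseSurfaceModel(design, response, terms).fit()
        pvals = fit.anova["p"]
        candidates = [
            (float(pvals[t]), t)
            for t in terms
            if t != "1"
            and not (hierarchy and _is_protected(t, terms))
            and np.isfinite(pvals[t])
            and pvals[t] > alpha
        ]
        if not candidates:
            fit.elimination_trace = trace
            return fit
        pmax, drop = max(candidates)
        trace.append({"dropped": drop, "p": pmax,
                      "terms_after": [t for t in terms if t != drop]})
        terms.remove(drop)
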