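"""Response-surface OLS fitting, ANOVA identities and model reduction."""

import numpy as np
import pytest

from nanoform import (
    SurfaceTruth,
    fit_rsm,
    gen_rsm_dataset,
    predicted_r2,
    pure_error,
    reduce_model,
)
from nanoform.datasets import CBD_SLN_TERMS
from nanoform.rsm import (
    TERM_UNIVERSE,
    ResponseSurfaceModel,
    SingularFitError,
    term_columns,
)

from conftest import ols_oracle


# ---------------------------------------------------------------------------
# OLS against the brute-force oracle

@pytest.mark.parametrize("response", ["Y1", "Y2", "Y3", "Y4"])
def test_ols_equals_normal_equations_oracle(study_design, response):
    terms = CBD_SLN_TERMS[response]
    fit = fit_rsm(study_design, response, terms)
    X = term_columns(study_design.coded, terms).to_numpy()
    beta = ols_oracle(X, study_design.response(response))
    np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)


def test_noise_free_synthetic_coefficients_recovered(empty_bbd):
    truth = SurfaceTruth(
        {"1": 1.36, "A": -0.3425, "B": -0.0338, "C": 0.5163,
         "AC": -0.125, "BC": -0.0175, "A^2": 0.0979},
        noise_sd=0.0,
    )
    d = gen_rsm_dataset(empty_bbd, truth, response="Y")
    fit = fit_rsm(d, "Y", list(truth.coefficients))
    for t, b in truth.coefficients.items():
        assert fit.params[t] == pytest.approx(b, abs=1e-10)


# ---------------------------------------------------------------------------
# refits of the published reduced models

def test_drug_loading_refit_matches_published_equation(study_design):
    fit = fit_rsm(study_design, "Y4", CBD_SLN_TERMS["Y4"])
    assert fit.params["AC"] == pytest.approx(-0.1250, abs=1e-6)
    assert fit.params["BC"] == pytest.approx(-0.0175, abs=1e-6)
    assert fit.params["C"] == pytest.approx(0.5163, rel=0.01)
    assert fit.params["A"] == pytest.approx(-0.3425, rel=0.01)
    assert round(float(fit.params["1"]), 2) == 1.36


def test_size_refit_matches_published_equation(study_design):
    fit = fit_rsm(study_design, "Y1", CBD_SLN_TERMS["Y1"])
    assert fit.params["B"] == pytest.approx(-35.20, rel=0.01)
    assert fit.params["C"] == pytest.approx(-33.95, rel=0.01)


def test_pdi_refit_matches_published_interaction(study_design):
    fit = fit_rsm(study_design, "Y2", CBD_SLN_TERMS["Y2"])
    assert fit.params["AB"] == pytest.approx(-0.0913, rel=0.01)


def test_orthogonality_makes_estimates_invariant_to_other_terms(study_design):
    """On the coded BBD, linear/interaction estimates do not move when any
    other linear or interaction term is dropped."""
    full = fit_rsm(study_design, "Y1", TERM_UNIVERSE)
    for dropped in ("A", "B", "C", "AB", "AC", "BC"):
        reduced = [t for t in TERM_UNIVERSE if t != dropped]
        fit = fit_rsm(study_design, "Y1", reduced)
        for t in ("A", "B", "C", "AB", "AC", "BC"):
            if t != dropped:
                assert fit.params[t] == pytest.approx(full.params[t], abs=1e-10)


# ---------------------------------------------------------------------------
# ANOVA identities and pure error

def test_pure_error_of_center_replicates(study_design):
    # center sizes 139, 138, 136 -> SS = 14/3, df = 2
    ss, df = pure_error(study_design, "Y1")
    assert ss == pytest.approx(14.0 / 3.0, abs=1e-9)
    assert df == 2


def test_pure_error_degenerate_cases(factors, empty_bbd):
    d = empty_bbd.with_response("Y", np.arange(15.0))
    d.responses.iloc[12:15, 0] = 5.0  # equal replicates -> SS = 0
    ss, df = pure_error(d, "Y")
    assert ss == 0.0 and df == 2
    edge_only = d.coded.iloc[:12]
    from nanoform.doe import DesignTable

    d12 = DesignTable(d.factors, edge_only.copy(),
                      responses=d.responses.iloc[:12].copy())
    with pytest.warns(UserWarning):
        ss, df = pure_error(d12, "Y")
    assert (ss, df) == (0.0, 0)


@pytest.mark.parametrize("response", ["Y1", "Y2", "Y3", "Y4"])
def test_anova_decomposition_identities(study_design, response):
    fit = fit_rsm(study_design, response, CBD_SLN_TERMS[response])
    assert fit.ss_model + fit.ss_resid == pytest.approx(fit.ss_total, rel=1e-8)
    assert fit.ss_lack_of_fit + fit.ss_pure_error == pytest.approx(
        fit.ss_resid, rel=1e-8, abs=1e-12
    )
    assert 0.0 <= fit.rsquared <= 1.0
    assert fit.rsquared_adj <= fit.rsquared


def test_adding_terms_never_decreases_r2(study_design):
    r2 = -np.inf
    terms = ["1"]
    for t in ("A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2"):
        terms.append(t)
        fit = fit_rsm(study_design, "Y1", terms)
        assert fit.rsquared >= r2 - 1e-12
        r2 = fit.rsquared


# ---------------------------------------------------------------------------
# predicted R^2 / PRESS

def test_press_matches_leave_one_out_refit_oracle(study_design):
    terms = CBD_SLN_TERMS["Y4"]
    fit = fit_rsm(study_design, "Y4", terms)
    X = term_columns(study_design.coded, terms).to_numpy()
    y = study_design.response("Y4")
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        beta = ols_oracle(X[keep], y[keep])
        press += (y[i] - X[i] @ beta) ** 2
    assert fit.press == pytest.approx(press, rel=1e-8)
    assert fit.rsquared_pred == pytest.approx(1.0 - press / fit.ss_total, rel=1e-8)
    assert predicted_r2(fit) == pytest.approx(fit.rsquared_pred, rel=1e-12)


def test_intercept_only_predicted_r2_is_negative(empty_bbd):
    d = empty_bbd.with_response("Y", np.r_[np.ones(7), -np.ones(8)])
    fit = fit_rsm(d, "Y", ["1"])
    assert fit.rsquared_pred <= 0.0


def test_saturated_model_leaves_no_loo_information(factors):
    from nanoform.doe import DesignTable
    import pandas as pd

    # 4 runs, 4 params -> hat diagonals all 1
    coded = pd.DataFrame(
        [[-1, -1, 1], [1, -1, -1], [-1, 1, -1], [1, 1, 1]],
        columns=[f.name for f in factors], dtype=float,
    )
    d = DesignTable(factors, coded).with_response("Y", [1.0, 2.0, 3.0, 4.0])
    fit = fit_rsm(d, "Y", ["1", "A", "B", "C"])
    assert np.isnan(fit.rsquared_pred)
    with pytest.raises(ZeroDivisionError):
        predicted_r2(fit)


# ---------------------------------------------------------------------------
# model reduction

@pytest.mark.parametrize("response", ["Y1", "Y2", "Y3", "Y4"])
def test_backward_elimination_recovers_published_term_sets(study_design, response):
    fit = reduce_model(study_design, response, alpha=0.05)
    assert fit.terms == CBD_SLN_TERMS[response]


def test_reduction_on_linear_truth_eliminates_higher_terms(empty_bbd):
    truth = SurfaceTruth({"1": 10.0, "A": 2.0, "B": -1.5, "C": 3.0},
                         noise_sd=0.01, seed=42)
    d = gen_rsm_dataset(empty_bbd, truth, response="Y")
    fit = reduce_model(d, "Y", alpha=0.05)
    assert fit.terms == ("1", "A", "B", "C")
    assert [s["dropped"] for s in fit.elimination_trace]  # trace recorded


def test_reduction_rejects_bad_alpha(study_design):
    with pytest.raises(ValueError):
        reduce_model(study_design, "Y1", alpha=0.0)


# ---------------------------------------------------------------------------
# error handling

def test_singular_matrix_names_collinear_terms(empty_bbd):
    from nanoform.doe import DesignTable

    coded = empty_bbd.coded.copy()
    coded["CBD"] = coded["GMS"]  # factor C duplicates A -> rank deficient
    dd = DesignTable(empty_bbd.factors, coded).with_response("Y", np.arange(15.0))
    with pytest.raises(SingularFitError, match="C"):
        fit_rsm(dd, "Y", ["1", "A", "B", "C"])


def test_missing_response_raises(empty_bbd):
    with pytest.raises(KeyError):
        fit_rsm(empty_bbd, "Y9", ["1", "A"])


def test_constant_response_degenerate(empty_bbd):
    d = empty_bbd.with_response("Y", np.full(15, 7.0))
    with pytest.warns(UserWarning):
        fit = fit_rsm(d, "Y", ["1", "A", "B", "C"])
    np.testing.assert_allclose(fit.params[["A", "B", "C"]], 0.0, atol=1e-12)
    assert np.isnan(fit.anova.loc["Model", "F"])


# ---------------------------------------------------------------------------
# coefficient recovery under noise

def test_coefficient_estimates_unbiased_over_seeds(empty_bbd):
    """Mean estimate over 500 seeded replicates within 3 SE of truth."""
    truth_coefs = {"1": 1.36, "A": -0.34, "C": 0.52, "AC": -0.125}
    sigma = 0.02
    terms = list(truth_coefs)
    X = term_columns(empty_bbd.coded, terms).to_numpy()
    n_rep = 500
    estimates = np.empty((n_rep, len(terms)))
    for s in range(n_rep):
        d = gen_rsm_dataset(
            empty_bbd, SurfaceTruth(truth_coefs, noise_sd=sigma, seed=s), "Y"
        )
        estimates[s] = fit_rsm(d, "Y", terms).params.to_numpy()
    xtx_inv = np.linalg.inv(X.T @ X)
    se_mean = sigma * np.sqrt(np.diag(xtx_inv)) / np.sqrt(n_rep)
    bias = estimates.mean(axis=0) - np.array(list(truth_coefs.values()))
    assert np.all(np.abs(bias) < 3 * se_mean)
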