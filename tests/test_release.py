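"""Cumulative-release arithmetic and kinetic model fitting/selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoform import (
    ReleaseCurve,
    classify_exponent,
    cumulative_release,
    fit_all_models,
    fit_kinetic,
    gen_release_curve,
    information_criteria,
    select_model,
)
from nanoform.release import KineticFitResult, ModelSelectionError

T_STD = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])


# ---------------------------------------------------------------------------
# cumulative release

def test_first_point_has_no_correction():
    c = ReleaseCurve(times=[1.0], conc=[0.001], Ve=1, Vo=200, m=1)
    assert cumulative_release(c)[0] == pytest.approx(20.0)


def test_later_points_add_back_sampled_aliquots():
    c = ReleaseCurve(times=[1.0, 2.0], conc=[0.001, 0.002], Ve=1, Vo=200, m=1)
    np.testing.assert_allclose(cumulative_release(c), [20.0, 40.1])


def test_zero_sampling_volume_is_plain_normalization():
    c = ReleaseCurve(times=[1.0, 2.0], conc=[0.001, 0.002], Ve=0, Vo=200, m=1)
    np.testing.assert_allclose(cumulative_release(c), [20.0, 40.0])


def test_monotone_concentrations_give_monotone_release():
    conc = np.linspace(0.0005, 0.004, 8)
    c = ReleaseCurve(times=np.arange(1.0, 9.0), conc=conc, Ve=1, Vo=200, m=1)
    assert np.all(np.diff(cumulative_release(c)) >= 0)


@pytest.mark.parametrize("kwargs", [{"m": 0.0}, {"Vo": 0.0}, {"Ve": -1.0}])
def test_invalid_vessel_parameters_rejected(kwargs):
    base = dict(times=[1.0], conc=[0.001], Ve=1.0, Vo=200.0, m=1.0)
    base.update(kwargs)
    with pytest.raises(ValueError):
        ReleaseCurve(**base)


def test_non_increasing_times_rejected():
    with pytest.raises(ValueError):
        ReleaseCurve(times=[1.0, 1.0], conc=[0.001, 0.001])


# ---------------------------------------------------------------------------
# kinetic fitting

def test_noise_free_korsmeyer_peppas_recovery():
    cr = 21.174 * T_STD**0.410
    fit = fit_kinetic("korsmeyer_peppas", T_STD, cr)
    assert fit.params["KKP"] == pytest.approx(21.174, abs=1e-6)
    assert fit.params["n"] == pytest.approx(0.410, abs=1e-6)
    assert fit.exponent_class == "quasi-Fickian diffusion"


def test_noise_free_first_order_recovery_and_selection():
    cr = 100.0 * (1.0 - np.exp(-0.314 * T_STD))
    fit = fit_kinetic("first_order", T_STD, cr)
    assert fit.params["K1"] == pytest.approx(0.314, abs=1e-6)
    results = fit_all_models(T_STD, cr)
    best = select_model(results)
    assert best.model == "first_order"
    kp = next(r for r in results if r.model == "korsmeyer_peppas")
    assert kp.msc < fit.msc


def test_fit_invariant_to_point_order():
    cr = 21.174 * T_STD**0.410
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(T_STD))
    a = fit_kinetic("korsmeyer_peppas", T_STD, cr)
    b = fit_kinetic("korsmeyer_peppas", T_STD[perm], cr[perm])
    assert a.params == b.params


def test_constant_release_is_degenerate():
    fit = fit_kinetic("zero_order", T_STD, np.full_like(T_STD, 50.0))
    assert np.isnan(fit.r2)
    assert not fit.converged


def test_time_zero_points_are_dropped():
    t = np.r_[0.0, T_STD]
    cr = np.r_[0.0, 21.174 * T_STD**0.410]
    fit = fit_kinetic("korsmeyer_peppas", t, cr)
    assert fit.n_points == len(T_STD)
    assert fit.params["n"] == pytest.approx(0.410, abs=1e-6)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        fit_kinetic("korsmeyer_peppas", [1.0, 2.0], [10.0, 15.0])


# ---------------------------------------------------------------------------
# information criteria

def test_information_criteria_formula_values():
    r2, aic, msc = information_criteria(63.2, 632.0, 8, 2)
    assert aic == pytest.approx(8 * np.log(63.2) + 4, abs=1e-10)
    assert r2 == pytest.approx(0.9)
    assert msc == pytest.approx(np.log(10.0) - 0.5, abs=1e-10)


def test_information_criteria_identities():
    # SSR == SST -> R2 = 0, MSC = -2p/n
    r2, _, msc = information_criteria(10.0, 10.0, 8, 2)
    assert r2 == 0.0 and msc == pytest.approx(-0.5)
    # halving SSR lowers AIC by n ln 2
    _, a1, _ = information_criteria(10.0, 40.0, 8, 2)
    _, a2, _ = information_criteria(5.0, 40.0, 8, 2)
    assert a1 - a2 == pytest.approx(8 * np.log(2.0), abs=1e-10)


def test_perfect_fit_sentinels():
    r2, aic, msc = information_criteria(0.0, 10.0, 8, 2)
    assert r2 == 1.0 and aic == -np.inf and msc == np.inf


def test_msc_r2_identity_for_stored_fits():
    """MSC = -ln(1 - R2) - 2p/n for every fitted model."""
    cr = 21.174 * T_STD**0.410 + np.random.default_rng(1).normal(0, 1.0, len(T_STD))
    for fit in fit_all_models(T_STD, np.clip(cr, 0, 100)):
        if np.isfinite(fit.msc):
            expected = -np.log(1.0 - fit.r2) - 2.0 * fit.n_params / fit.n_points
            assert fit.msc == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# exponent classification

@pytest.mark.parametrize(
    "n,label",
    [
        (0.395, "quasi-Fickian diffusion"),
        (0.45, "Fickian diffusion"),
        (0.60, "non-Fickian (anomalous) transport"),
        (0.89, "case II (zero-order) transport"),
        (1.2, "super case II transport"),
        (0.45 + 5e-10, "Fickian diffusion"),  # equality tolerance
    ],
)
def test_exponent_classification_thresholds(n, label):
    assert classify_exponent(n) == label


def test_exponent_must_be_finite():
    with pytest.raises(ValueError):
        classify_exponent(float("nan"))


# ---------------------------------------------------------------------------
# model selection

def test_selection_prefers_generating_model_under_noise():
    cr = gen_release_curve(
        "first_order", {"K1": 0.314}, T_STD, sigma=0.5, seed=0
    ).cumulative()
    results = fit_all_models(T_STD, cr)
    best = select_model(results)
    # oracle: exhaustive criterion comparison
    oracle = max(
        (r for r in results if r.converged), key=lambda r: r.msc
    )
    assert best.model == oracle.model == "first_order"


def test_tie_broken_by_fewer_parameters():
    a = KineticFitResult("korsmeyer_peppas", {"KKP": 10, "n": 1}, 0.99, 10.0,
                         3.0, 7, 2, 1.0, 100.0)
    b = KineticFitResult("zero_order", {"K0": 10}, 0.99, 10.0, 3.0, 7, 1,
                         1.0, 100.0)
    assert select_model([a, b]).model == "zero_order"
    assert select_model([b, a]).model == "zero_order"


def test_selection_requires_converged_fits():
    bad = KineticFitResult("zero_order", {"K0": 1}, np.nan, np.nan, np.nan,
                           7, 1, 1.0, 0.0, converged=False)
    with pytest.raises(ModelSelectionError):
        select_model([bad])


# ---------------------------------------------------------------------------
# parameter recovery property

def test_kp_exponent_recovery_under_noise():
    """Median |n_hat - n| < 0.02 over 200 seeded noisy curves (sigma = 1%)."""
    errs = []
    for seed in range(200):
        curve = gen_release_curve(
            "korsmeyer_peppas", {"KKP": 21.174, "n": 0.410}, T_STD,
            sigma=1.0, seed=seed,
        )
        fit = fit_kinetic("korsmeyer_peppas", curve.times, curve.cumulative())
        errs.append(abs(fit.params["n"] - 0.410))
    assert np.median(errs) < 0.02


@settings(max_examples=50, deadline=None)
@given(
    k=st.floats(5.0, 25.0),
    n=st.floats(0.1, 0.9),
)
def test_kp_noise_free_recovery_property(k, n):
    cr = k * T_STD**n
    if cr.max() > 100:
        return
    fit = fit_kinetic("korsmeyer_peppas", T_STD, cr)
    assert fit.params["KKP"] == pytest.approx(k, rel=1e-5)
    assert fit.params["n"] == pytest.approx(n, abs=1e-5)
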