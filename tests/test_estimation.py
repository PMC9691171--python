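import numpy as np
import pandas as pd
import pytest

from needsel.design import DesignMatrices
from needsel.model import (EstimationError, SeparationError, _pilot_probit,
                           fit_model, hosmer_lemeshow, information_criteria,
                           sandwich_vcov)


# ----------------------------------------------------------- fit statistics
def test_information_criteria_arithmetic():
    aic, bic = information_criteria(-100.0, 10, 100)
    assert aic == pytest.approx(220.0)
    assert bic == pytest.approx(200 + 10 * np.log(100))
    with pytest.raises(ValueError):
        information_criteria(-100.0, 0, 100)
    with pytest.raises(ValueError):
        information_criteria(-100.0, 3, 0)


# --------------------------------------------------------- Hosmer–Lemeshow
def test_hosmer_lemeshow_hand_computed_two_groups():
    # group A: n=10, mean risk .2, 3 events; group B: n=10, mean risk .7, 6
    y = np.r_[np.ones(3), np.zeros(7), np.ones(6), np.zeros(4)]
    p = np.r_[np.full(10, 0.2), np.full(10, 0.7)]
    stat, df, _ = hosmer_lemeshow(y, p, groups=2)
    assert stat == pytest.approx(1 / (10 * 0.2 * 0.8) + 1 / (10 * 0.7 * 0.3),
                                 rel=1e-12)


def test_hosmer_lemeshow_perfect_calibration_is_zero():
    y = np.r_[np.ones(2), np.zeros(8), np.ones(5), np.zeros(5)]
    p = np.r_[np.full(10, 0.2), np.full(10, 0.5)]
    stat, df, pval = hosmer_lemeshow(y, p, groups=2)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_input_validation():
    with pytest.raises(ValueError):
        hosmer_lemeshow([0, 1], [0.0, 0.5])
    with pytest.raises(ValueError):
        hosmer_lemeshow([0, 1], [0.2, 0.5], groups=1)


# ------------------------------------------------------------ sandwich vcov
def test_sandwich_reduces_to_heteroskedasticity_robust_form():
    rng = np.random.default_rng(0)
    n, k = 40, 3
    S = rng.standard_normal((n, k))
    H = -np.eye(k) * n
    V = sandwich_vcov(S, H, cluster_ids=np.arange(n), weights=np.ones(n))
    expected = np.linalg.inv(-H) @ (S.T @ S) @ np.linalg.inv(-H)
    assert np.allclose(V, expected)


def test_sandwich_invariant_to_row_duplication_with_halved_weights():
    rng = np.random.default_rng(1)
    n, k = 30, 2
    S = rng.standard_normal((n, k))
    ids = rng.integers(0, 10, n)
    H = -(np.eye(k) * 50 + 0.1)
    V1 = sandwich_vcov(S, H, ids, np.ones(n))
    S2 = np.repeat(S, 2, axis=0)
    ids2 = np.repeat(ids, 2)
    V2 = sandwich_vcov(S2, H, ids2, np.full(2 * n, 0.5))
    assert np.allclose(V1, V2)


def test_sandwich_matches_hand_assembly_three_clusters():
    S = np.array([[1.0, 0.5], [-0.5, 1.0],
                  [0.2, -0.3], [0.1, 0.4],
                  [-1.0, 0.2], [0.3, -0.6]])
    w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 1.0])
    ids = np.array(["a", "a", "b", "b", "c", "c"])
    H = np.array([[-5.0, 1.0], [1.0, -4.0]])
    B = np.zeros((2, 2))
    for c in "abc":
        g = ((w[ids == c])[:, None] * S[ids == c]).sum(axis=0)
        B += np.outer(g, g)
    Ainv = np.linalg.inv(-H)
    assert np.allclose(sandwich_vcov(S, H, ids, w), Ainv @ B @ Ainv)


# ------------------------------------------------------------------ fitting
def test_fit_smoke_and_reporting_scale(small_fit, small_design):
    fit = small_fit
    assert fit.converged
    assert fit.n_obs == small_design.n_obs
    assert fit.n_individuals == small_design.n_individuals
    eig = np.linalg.eigvalsh(fit.vcov)
    assert eig.min() > -1e-8  # robust covariance is PSD
    k = len(fit.free_values)
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
    assert fit.bic == pytest.approx(-2 * fit.loglik + k * np.log(fit.n_obs))
    tab = fit.summary_frame()
    assert len(tab) == k
    row = tab[(tab.equation == "needs") & (tab.term == "age_c")].iloc[0]
    j = fit.free_names.index("eq1:age_c")
    # display scale: age row multiplied by 10, z unchanged
    assert row["coeff"] == pytest.approx(10 * fit.free_values[j])
    se = np.sqrt(fit.vcov[j, j])
    assert row["robust_se"] == pytest.approx(10 * se)
    assert row["z"] == pytest.approx(fit.free_values[j] / se)
    assert 0 <= row["p_value"] <= 1


def test_fixed_rho_fit_factorizes(small_design):
    """With rho pinned at zero the joint likelihood is probit x independent
    MNP: each observation's log-probability splits into a selection part and
    a conditional-choice part, and the fit cannot fall below the pilots."""
    from scipy.special import ndtr

    from needsel.ghk import ParameterVector, SelectionLikelihood

    fit = fit_model(small_design, n_draws=60, seed=3, fix_rho=(0.0, 0.0, 0.0))
    assert np.allclose(fit.params.rho, 0.0)
    # well-identified coefficients stay at the pilots
    assert np.allclose(fit.params.beta2, fit.pilot["beta2"], atol=0.02)
    # factorization of the simulated likelihood itself
    lik = SelectionLikelihood(small_design, n_draws=400, seed=9)
    pv = ParameterVector(fit.params.beta1, fit.params.beta2, np.zeros(3))
    logp = lik.logp_obs(pv)
    eta1 = small_design.X1 @ pv.beta1
    sel = small_design.y1 == 1
    assert np.allclose(logp[~sel], np.log(ndtr(-eta1[~sel])), atol=1e-12)
    # selected observations: joint = Phi(eta1) * P(region)
    far = ParameterVector(pv.beta1 + 40 * np.eye(1, len(pv.beta1))[0],
                          pv.beta2, np.zeros(3))
    region = SelectionLikelihood(small_design, n_draws=400, seed=9).logp_obs(far)
    expected = np.log(ndtr(eta1[sel])) + region[sel]
    assert np.allclose(logp[sel], expected, atol=5e-3)
    # the joint optimum cannot be worse than the pilot starting point
    start = ParameterVector(fit.pilot["beta1"], fit.pilot["beta2"], np.zeros(3))
    lik_fit = SelectionLikelihood(small_design, n_draws=60, seed=3)
    assert lik_fit.w @ lik_fit.logp_obs(fit.params) >= \
        lik_fit.w @ lik_fit.logp_obs(start) - 1e-9


def test_degenerate_outcome_groups_raise():
    n = 50
    base = dict(X1=np.ones((n, 1)), X2=np.ones((n, 1)),
                weights=np.ones(n), cluster_ids=np.arange(n),
                eq1_names=["const"], eq2_names=["const"])
    all_needs = DesignMatrices(y1=np.ones(n, dtype=int),
                               y2=np.ones(n), **base)
    with pytest.raises(EstimationError):
        fit_model(all_needs, n_draws=20, seed=0)
    no_needs = DesignMatrices(y1=np.zeros(n, dtype=int),
                              y2=np.full(n, np.nan), **base)
    with pytest.raises(EstimationError, match="needs"):
        fit_model(no_needs, n_draws=20, seed=0)


def test_pilot_probit_detects_separation():
    x = np.linspace(-2, 2, 60)
    X = np.column_stack([np.ones(60), x])
    y = (x > 0).astype(int)
    with pytest.raises(SeparationError):
        _pilot_probit(X, y, np.ones(60))
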