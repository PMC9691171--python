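import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import multivariate_normal as mvn

from needsel.design import DesignMatrices
from needsel.ghk import (IID_OMEGA, ParameterVector, SelectionLikelihood,
                         alternative_region, choice_probabilities,
                         ghk_mvn_rectangle, log_likelihood)
from needsel.ghk import NotPositiveDefiniteError


def zero_params(rho=(0.0, 0.0, 0.0)):
    return ParameterVector(np.zeros(2), np.zeros((3, 2)), np.asarray(rho))


# ---------------------------------------------------------------- rectangle
def test_one_dimensional_half_line_is_exact_normal_cdf():
    p = ghk_mvn_rectangle([-np.inf], [0.0], [[1.0]], n_draws=1, seed=0)
    assert p == 0.5
    p = ghk_mvn_rectangle([-np.inf], [1.3], [[4.0]], n_draws=1, seed=0)
    assert p == pytest.approx(ndtr(1.3 / 2.0), abs=0)


def test_bivariate_orthant_closed_form():
    # P(u1>0, u2>0) = 1/4 + arcsin(rho)/(2 pi) = 1/3 at rho = 0.5
    p = ghk_mvn_rectangle([0, 0], [np.inf, np.inf],
                          [[1, 0.5], [0.5, 1]], n_draws=500, seed=1)
    assert p == pytest.approx(1 / 3, abs=0.003)


def test_random_rectangles_match_genz_integration():
    rng = np.random.default_rng(5)
    for k in range(10):
        A = rng.standard_normal((4, 4))
        cov = A @ A.T + 0.5 * np.eye(4)
        lo = rng.uniform(-2, 0, 4) * np.sqrt(np.diag(cov))
        hi = lo + rng.uniform(0.5, 3.0, 4) * np.sqrt(np.diag(cov))
        ghk = ghk_mvn_rectangle(lo, hi, cov, n_draws=500, seed=k)
        exact = mvn.cdf(hi, mean=np.zeros(4), cov=cov, lower_limit=lo)
        assert ghk == pytest.approx(exact, abs=0.005)


def test_non_positive_definite_covariance_raises():
    with pytest.raises(NotPositiveDefiniteError):
        ghk_mvn_rectangle([0, 0], [1, 1], [[1, 2], [2, 1]])


# ------------------------------------------------------------ choice regions
def test_reference_region_at_zero_utilities():
    reg = alternative_region(1, np.zeros((3, 2)), np.zeros(2))
    assert np.array_equal(reg.M, -np.eye(3))
    assert np.array_equal(reg.c, np.zeros(3))


def test_alternative_two_region_inequalities():
    eta = np.array([0.4, -0.2, 0.1])
    x2 = np.array([1.0])
    reg = alternative_region(2, eta.reshape(3, 1), x2)
    assert np.array_equal(reg.M, [[1, 0, 0], [1, -1, 0], [1, 0, -1]])
    # u2 > -0.4; u2-u3 > -0.2-0.4... i.e. c = (eta2, eta2-eta3, eta2-eta4)
    assert np.allclose(reg.c, [0.4, 0.6, 0.3])
    assert np.linalg.matrix_rank(reg.M) == 3
    with pytest.raises(ValueError):
        alternative_region(5, eta.reshape(3, 1), x2)


def test_exchangeable_alternatives_split_evenly():
    pn, pj = choice_probabilities(zero_params(), [0, 0], [0, 0],
                                  n_draws=500, seed=3)
    assert pn == 0.5  # exact: Phi(0)
    assert np.allclose(pj, 0.125, atol=0.002)
    assert pn + pj.sum() == pytest.approx(1.0, abs=0.004)


def test_zero_correlation_factorizes():
    params = ParameterVector(np.array([0.7, 0.3]), np.array(
        [[0.2, -0.1], [0.4, 0.0], [-0.3, 0.2]]))
    x1, x2 = np.array([1.0, 1.0]), np.array([1.0, 0.5])
    pn, pj = choice_probabilities(params, x1, x2, n_draws=4000, seed=4)
    # region probabilities: push the selection index to certainty
    far = ParameterVector(np.array([30.0, 0.0]), params.beta2)
    _, pregion = choice_probabilities(far, x1, x2, n_draws=4000, seed=4)
    psel = ndtr(x1 @ params.beta1)
    assert np.allclose(pj, psel * pregion, atol=0.003)


def test_selection_correlation_matches_monte_carlo():
    params = ParameterVector(np.array([0.5, 0.2]), np.array(
        [[0.3, -0.2], [-0.1, 0.4], [0.2, 0.1]]),
        rho=np.array([0.4, -0.2, 0.3]))
    x1, x2 = np.array([1.0, 0.8]), np.array([1.0, -0.5])
    pn, pj = choice_probabilities(params, x1, x2, n_draws=2000, seed=9)
    rng = np.random.default_rng(99)
    z = rng.multivariate_normal(np.zeros(4), params.joint_cov(), 1_000_000)
    eta1 = x1 @ params.beta1
    eta2 = params.beta2 @ x2
    sel = z[:, 0] > -eta1
    util = np.column_stack([np.zeros(len(z)), eta2 + z[:, 1:]])
    ch = util.argmax(axis=1) + 1
    emp = np.array([(sel & (ch == j)).mean() for j in (1, 2, 3, 4)])
    assert pn == pytest.approx((~sel).mean(), abs=0.003)
    assert np.allclose(pj, emp, atol=0.003)


def test_probability_normalization_over_random_parameters():
    rng = np.random.default_rng(11)
    for _ in range(5):
        params = ParameterVector(rng.normal(0, 0.5, 2),
                                 rng.normal(0, 0.5, (3, 2)),
                                 rho=rng.uniform(-0.4, 0.4, 3))
        pn, pj = choice_probabilities(params, rng.normal(0, 1, 2),
                                      rng.normal(0, 1, 2),
                                      n_draws=1000, seed=12)
        assert pn + pj.sum() == pytest.approx(1.0, abs=0.01)


def test_increasing_selection_intercept_increases_needs_probability():
    x1, x2 = np.array([1.0, 0.4]), np.array([1.0, 0.4])
    beta2 = np.array([[0.2, 0.1], [0.0, -0.3], [0.1, 0.0]])
    prev = -1.0
    for b0 in (-1.0, 0.0, 1.0, 2.0):
        params = ParameterVector(np.array([b0, 0.3]), beta2,
                                 rho=np.array([0.2, 0.2, 0.2]))
        pn, pj = choice_probabilities(params, x1, x2, n_draws=500, seed=13)
        assert 1.0 - pn > prev
        prev = 1.0 - pn


# ------------------------------------------------------------ parameter type
def test_parameter_vector_validation_and_round_trip(tmp_path):
    with pytest.raises(ValueError, match="scale normalization"):
        ParameterVector(np.zeros(1), np.zeros((3, 1)), omega=np.eye(3))
    bad = ParameterVector(np.zeros(1), np.zeros((3, 1)),
                          rho=np.array([0.99, 0.99, -0.99]))
    with pytest.raises(NotPositiveDefiniteError):
        bad.joint_cov()
    pv = ParameterVector(np.array([1.2, -0.3]),
                         np.arange(6, dtype=float).reshape(3, 2) / 10,
                         rho=np.array([0.1, 0.2, 0.3]))
    path = tmp_path / "params.tsv"
    pv.to_text(path, ["const", "x"], ["const", "z"])
    back = ParameterVector.from_text(path)
    assert np.allclose(back.beta1, pv.beta1)
    assert np.allclose(back.beta2, pv.beta2)
    assert np.allclose(back.rho, pv.rho)
    assert np.allclose(back.omega, IID_OMEGA)


# ---------------------------------------------------------------- likelihood
def tiny_design(y1, y2, weights=None):
    n = len(y1)
    return DesignMatrices(
        X1=np.ones((n, 1)), X2=np.ones((n, 1)),
        y1=np.asarray(y1), y2=np.asarray(y2, dtype=float),
        weights=np.asarray(weights if weights is not None else np.ones(n),
                           dtype=float),
        cluster_ids=np.arange(n), eq1_names=["const"], eq2_names=["const"])


def test_single_nonneeds_contribution_is_log_half():
    d = tiny_design([0], [np.nan])
    pv = ParameterVector(np.zeros(1), np.zeros((3, 1)))
    total, contrib = log_likelihood(pv, d, n_draws=50, seed=0)
    assert total == pytest.approx(np.log(0.5))
    assert contrib[0] == pytest.approx(np.log(0.5))


def test_loglik_linear_in_weights():
    d = tiny_design([0, 1, 1, 1, 1], [np.nan, 1, 2, 3, 4])
    pv = ParameterVector(np.array([0.3]), np.array([[0.1], [-0.2], [0.0]]),
                         rho=np.array([0.2, 0.2, 0.2]))
    base, _ = log_likelihood(pv, d, n_draws=200, seed=1)
    d2 = tiny_design([0, 1, 1, 1, 1], [np.nan, 1, 2, 3, 4],
                     weights=2 * np.ones(5))
    double, _ = log_likelihood(pv, d2, n_draws=200, seed=1)
    assert double == pytest.approx(2 * base, rel=1e-12)


def test_seed_stability_is_bitwise():
    d = tiny_design([0, 1, 1], [np.nan, 1, 3])
    pv = ParameterVector(np.array([0.3]), np.array([[0.1], [-0.2], [0.0]]),
                         rho=np.array([0.2, 0.2, 0.2]))
    a, ca = log_likelihood(pv, d, n_draws=100, seed=5)
    b, cb = log_likelihood(pv, d, n_draws=100, seed=5)
    assert a == b
    assert np.array_equal(ca, cb)


def test_likelihood_matches_genz_oracle_per_observation(small_design):
    """n=20 subsample: simulated log-probabilities vs deterministic
    integration of each observation's rectangle."""
    from needsel.ghk import _joint_chol, _region_lower

    d = small_design
    idx = np.arange(len(d.y1))[:20]
    sub = DesignMatrices(X1=d.X1[idx], X2=d.X2[idx], y1=d.y1[idx],
                         y2=d.y2[idx], weights=d.weights[idx],
                         cluster_ids=d.cluster_ids[idx],
                         eq1_names=d.eq1_names, eq2_names=d.eq2_names)
    from needsel.synthetic import default_truth

    truth = default_truth()  # realistic coefficient magnitudes
    pv = ParameterVector(truth.beta1, truth.beta2,
                         rho=np.array([0.3, 0.1, -0.2]))
    lik = SelectionLikelihood(sub, n_draws=5000, seed=3)
    logp = lik.logp_obs(pv)
    sigma = pv.joint_cov()
    eta1 = sub.X1 @ pv.beta1
    Eta2 = sub.X2 @ pv.beta2.T
    for i in range(len(idx)):
        if sub.y1[i] == 0:
            exact = ndtr(-eta1[i])
        else:
            j = int(sub.y2[i])
            chol = _joint_chol(j, sigma)
            lo = np.concatenate([[-eta1[i]], _region_lower(j, Eta2[[i]])[0]])
            # P(z > lo) = P(-z < -lo) with -z ~ N(0, C)
            exact = mvn.cdf(-lo, mean=np.zeros(4), cov=chol @ chol.T)
        assert logp[i] == pytest.approx(np.log(exact), abs=1e-3)


def test_unrestricted_omega_pack_round_trip():
    """The free-Cholesky parameterization keeps Omega[0,0]=2 fixed and
    reproduces an arbitrary valid covariance exactly."""
    d = tiny_design([0, 1, 1], [np.nan, 1, 3])
    lik = SelectionLikelihood(d, n_draws=20, seed=0, mode="unrestricted")
    omega = np.array([[2.0, 0.8, 0.5], [0.8, 1.5, 0.6], [0.5, 0.6, 2.5]])
    pv = ParameterVector(np.array([0.2]), np.array([[0.1], [0.0], [-0.1]]),
                         rho=np.array([0.1, -0.1, 0.2]), omega=omega)
    back = lik.unpack(lik.pack(pv))
    assert np.allclose(back.omega, omega)
    assert np.allclose(back.rho, pv.rho)
    assert lik.n_free == 1 + 3 * 1 + 3 + 5
    # iid mode refuses nothing but simply pins Omega
    lik_iid = SelectionLikelihood(d, n_draws=20, seed=0, mode="iid")
    assert np.allclose(lik_iid.unpack(lik_iid.pack(pv)).omega, IID_OMEGA)
    with pytest.raises(ValueError):
        SelectionLikelihood(d, n_draws=20, seed=0, mode="full")


def test_index_gradients_match_direct_differences(small_design):
    lik = SelectionLikelihood(small_design, n_draws=50, seed=4)
    rng = np.random.default_rng(8)
    pv = ParameterVector(rng.normal(0, 0.1, small_design.X1.shape[1]),
                         rng.normal(0, 0.1, (3, small_design.X2.shape[1])),
                         rho=np.array([0.1, 0.0, 0.2]))
    theta = lik.pack(pv)
    g = -lik.neg_grad(theta)
    f0 = -lik.neg_loglik(theta)
    for i in (0, 3, lik.k1 + 2, lik.k1 + 3 * lik.k2 + 1):
        tp = theta.copy()
        h = 1e-5
        tp[i] += h
        fd = (-lik.neg_loglik(tp) - f0) / h
        assert g[i] == pytest.approx(fd, rel=5e-3, abs=1e-4)
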