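"""Maximum simulated likelihood estimation with cluster-robust inference.

Estimation is pooled pseudo-maximum-likelihood: the panel enters as stacked
person-years, the longitudinal survey weights multiply each observation's
log-likelihood contribution, and dependence between the waves of one person
is handled through the clustered sandwich variance (scores summed within
individuals), not through random effects.  Fitting starts from pilot
estimates -- a weighted univariate probit for the selection equation and an
independent (iid-mode, zero-correlation) multinomial probit for the barrier
equation -- and then maximizes the GHK-simulated weighted log-likelihood by
quasi-Newton iterations under common random numbers.

The public surface is the scikit-learn style estimator
:class:`SelectionMultinomialProbit` plus functional wrappers
(:func:`fit_model`, :func:`sandwich_vcov`, :func:`hosmer_lemeshow`,
:func:`information_criteria`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm
from scipy.special import ndtr
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .design import DISPLAY_SCALE, DesignMatrices, ModelSpec, build_design
from .ghk import (IID_OMEGA, ParameterVector, SelectionLikelihood,
                  assemble_gradient, assemble_hessian, assemble_scores)

__all__ = [
    "FitResult",
    "EstimationError",
    "SeparationError",
    "SelectionMultinomialProbit",
    "fit_model",
    "pilot_fits",
    "sandwich_vcov",
    "hosmer_lemeshow",
    "information_criteria",
]


class EstimationError(RuntimeError):
    pass


class SeparationError(EstimationError):
    pass


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC and BIC: ``-2 loglik + 2k`` and ``-2 loglik + k ln(n)``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + 2.0 * k, -2.0 * loglik + k * np.log(n)


def sandwich_vcov(scores: np.ndarray, hessian: np.ndarray, cluster_ids,
                  weights: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich ``A^-1 B A^-1``.

    ``scores`` are per-observation *unweighted* scores of log p_i; ``hessian``
    is the weighted log-likelihood Hessian.  ``A = -hessian`` and ``B`` sums
    the weighted scores within each cluster before taking outer products, so
    intra-individual correlation is allowed for.
    """
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ws = scores * weights[:, None]
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    g = np.zeros((codes.max() + 1, scores.shape[1]))
    np.add.at(g, codes, ws)
    B = g.T @ g
    A = -np.asarray(hessian, dtype=float)
    try:
        Ainv = np.linalg.solve(A, np.eye(A.shape[0]))
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; using pseudo-inverse for the sandwich")
        Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv.T
    return (V + V.T) / 2.0


def hosmer_lemeshow(y, p, groups: int = 10):
    """Hosmer–Lemeshow grouped chi-square test of probit calibration.

    Observations are grouped into ``groups`` bins by deciles of fitted risk;
    the statistic is ``sum_g (O_g - n_g pbar_g)^2 / (n_g pbar_g (1-pbar_g))``
    on ``groups - 2`` degrees of freedom.  A group whose mean fitted risk is
    exactly 0 or 1 is merged with its neighbor (with a warning).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if groups < 2:
        raise ValueError("groups must be >= 2")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bins = np.searchsorted(np.unique(edges), p, side="right")
    cells = []
    for b in np.unique(bins):
        m = bins == b
        cells.append([y[m].sum(), m.sum(), p[m].mean()])
    merged = []
    for O, n_g, pbar in cells:  # merge degenerate cells into the previous one
        if merged and (pbar <= 0.0 or pbar >= 1.0):
            warnings.warn("merging a Hosmer–Lemeshow group with degenerate mean risk")
            pO, pn, pp = merged[-1]
            merged[-1] = [pO + O, pn + n_g, (pp * pn + pbar * n_g) / (pn + n_g)]
        else:
            merged.append([O, n_g, pbar])
    stat = 0.0
    for O, n_g, pbar in merged:
        stat += (O - n_g * pbar) ** 2 / (n_g * pbar * (1.0 - pbar))
    df = max(len(merged) - 2, 1)
    return float(stat), int(df), float(chi2.sf(stat, df))


@dataclass
class FitResult:
    """Estimates, robust covariance, fit statistics and the report table."""

    params: ParameterVector
    vcov: np.ndarray  # robust, over (beta1, beta2 rows, rho) in natural space
    loglik: float
    n_obs: int
    n_individuals: int
    converged: bool
    n_draws: int
    seed: int
    mode: str
    aic: float
    bic: float
    eq1_names: list
    eq2_names: list
    age_center: float
    grad_norm: float = np.nan
    pilot: dict = field(default_factory=dict)
    optimizer_message: str = ""

    @property
    def free_names(self) -> list:
        names = [f"eq1:{t}" for t in self.eq1_names]
        for lab in ("financial", "time", "lack"):
            names += [f"{lab}:{t}" for t in self.eq2_names]
        names += [f"rho:{lab}" for lab in ("financial", "time", "lack")]
        return names

    @property
    def free_values(self) -> np.ndarray:
        return np.concatenate([self.params.beta1, self.params.beta2.ravel(),
                               self.params.rho])

    def summary_frame(self) -> pd.DataFrame:
        """Per-term table (display scale): coefficient, robust SE, z, p."""
        se = np.sqrt(np.maximum(np.diag(self.vcov), 0.0))
        val = self.free_values
        rows = []
        terms = ([("needs", t) for t in self.eq1_names]
                 + [(lab, t) for lab in ("financial", "time", "lack")
                    for t in self.eq2_names]
                 + [("rho", lab) for lab in ("financial", "time", "lack")])
        for (eq, term), v, s in zip(terms, val, se):
            scale = DISPLAY_SCALE.get(term, 1.0)
            z = v / s if s > 0 else np.nan
            rows.append({"equation": eq, "term": term,
                         "coeff": v * scale, "robust_se": s * scale,
                         "z": z, "p_value": 2 * norm.sf(abs(z)) if s > 0 else np.nan})
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {
            "loglik": float(self.loglik), "aic": float(self.aic),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs), "n_individuals": int(self.n_individuals),
            "converged": bool(self.converged), "n_draws": self.n_draws,
            "seed": self.seed, "mode": self.mode,
            "grad_norm": float(self.grad_norm),
            "optimizer_message": self.optimizer_message,
        }


def _check_groups(y1: np.ndarray) -> None:
    if (y1 == 1).sum() == 0:
        raise EstimationError("no observations with healthcare needs; the "
                              "conditional equation is unidentifiable")
    if (y1 == 0).sum() == 0:
        raise EstimationError("no non-needs observations; the selection "
                              "equation is unidentifiable")


def _pilot_probit(X1: np.ndarray, y1: np.ndarray, w: np.ndarray) -> np.ndarray:
    model = sm.GLM(y1, X1, family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    beta = np.asarray(res.params)
    eta = X1 @ beta
    if np.min(eta[y1 == 1], initial=np.inf) > np.max(eta[y1 == 0], initial=-np.inf):
        raise SeparationError("pilot probit separates the outcome perfectly")
    return beta


_GH_NODES = 48


def _mnp_iid_logp(Eta2: np.ndarray, cat: np.ndarray) -> np.ndarray:
    """Exact iid-mode MNP log choice probabilities via Gauss–Hermite.

    ``Eta2`` is (n, 3) for alternatives 2..4 (reference alternative has index
    0 and zero utility); ``cat`` in {1,..,4}.  Utilities have iid standard
    normal errors, so P(j) = E_t[prod_{k != j} Phi(t + eta_j - eta_k)].
    """
    x, wq = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wq = wq / np.sqrt(2 * np.pi)
    n = Eta2.shape[0]
    eta = np.column_stack([np.zeros(n), Eta2])  # (n, 4)
    own = eta[np.arange(n), cat - 1]
    p = np.zeros(n)
    for t, wt in zip(x, wq):
        f = np.ones(n)
        for k in range(4):
            diff = own - eta[:, k] + t
            keep = cat - 1 != k
            f[keep] *= ndtr(diff[keep])
        p += wt * f
    return np.log(np.maximum(p, 1e-300))


def _pilot_mnp(X2: np.ndarray, cat: np.ndarray, w: np.ndarray,
               max_iter: int = 500) -> np.ndarray:
    """Weighted independent multinomial probit (iid mode, rho = 0) pilot."""
    s = X2.std(axis=0)
    s[s == 0] = 1.0
    X2 = X2 / s
    k2 = X2.shape[1]

    def unpack(th):
        return th.reshape(3, k2)

    def nll(th):
        return -float(w @ _mnp_iid_logp(X2 @ unpack(th).T, cat))

    def grad(th, h=1e-5):
        E = X2 @ unpack(th).T
        g = np.empty((3, k2))
        for j in range(3):
            Ep, Em = E.copy(), E.copy()
            Ep[:, j] += h
            Em[:, j] -= h
            d = (_mnp_iid_logp(Ep, cat) - _mnp_iid_logp(Em, cat)) / (2 * h)
            g[j] = X2.T @ (w * d)
        return -g.ravel()

    res = scipy.optimize.minimize(nll, np.zeros(3 * k2), jac=grad,
                                  method="L-BFGS-B",
                                  options={"maxiter": max_iter, "ftol": 1e-11})
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-2 * len(cat):
        warnings.warn(f"pilot multinomial probit did not fully converge: {res.message}")
    return unpack(res.x) / s


def pilot_fits(design: DesignMatrices) -> tuple[np.ndarray, np.ndarray]:
    """Pilot starting values: weighted probit (eq 1) and independent
    multinomial probit in iid mode with rho = 0 (eq 2)."""
    _check_groups(design.y1)
    w = design.weights / design.weights.mean()
    beta1 = _pilot_probit(design.X1, design.y1, w)
    sel = design.y1 == 1
    beta2 = _pilot_mnp(design.X2[sel], design.y2[sel].astype(int), w[sel])
    return beta1, beta2


def _scaled_design(design: DesignMatrices):
    """Unit-spread copy of the design for optimizer conditioning.

    Age polynomials put columns on wildly different scales (a squared
    centered age reaches ~2000 while dummies are 0/1), which cripples
    quasi-Newton steps; optimizing on rescaled columns and mapping the
    coefficients back is exact and costless.
    """
    def scales(X):
        s = X.std(axis=0)
        s[s == 0] = 1.0
        return s

    s1, s2 = scales(design.X1), scales(design.X2)
    scaled = DesignMatrices(
        X1=design.X1 / s1, X2=design.X2 / s2, y1=design.y1, y2=design.y2,
        weights=design.weights, cluster_ids=design.cluster_ids,
        eq1_names=design.eq1_names, eq2_names=design.eq2_names,
        age_center=design.age_center)
    return scaled, s1, s2


def _newton_msl(lik: SelectionLikelihood, theta0: np.ndarray, *,
                max_iter: int = 30, improve_tol: float = 1e-7,
                step_tol: float = 1e-7, free_mask: np.ndarray | None = None):
    """Damped Newton ascent on the simulated log-likelihood.

    Gradient and Hessian come from the index-space finite differences
    (one combined pass per iteration); the correlation coordinates ride
    through the atanh transform via the chain rule.  A Levenberg shift makes
    the curvature negative definite when needed and an Armijo backtracking
    line search (which also absorbs non-PD correlation proposals) guarantees
    the likelihood never decreases across accepted iterates.  On the
    converged iterate the index derivatives are returned for reuse in the
    sandwich, so the variance costs no extra likelihood sweeps.
    """
    X1, X2, w = lik.design.X1, lik.design.X2, lik.w
    k1, k2 = lik.k1, lik.k2
    r0 = k1 + 3 * k2
    theta = theta0.copy()
    pd_margin = 2e-3  # keep iterates inside PD so +-h perturbations stay valid

    def value(th):
        try:
            params = lik.unpack(th)
            if np.linalg.eigvalsh(params.joint_cov()).min() < pd_margin:
                return -np.inf
            return float(w @ lik.logp_obs(params))
        except np.linalg.LinAlgError:
            return -np.inf

    f = None
    converged = False
    stalls = 0
    info = {}
    for it in range(max_iter):
        params = lik.unpack(theta)
        try:
            base, D, D2 = lik.index_derivs(params)
        except np.linalg.LinAlgError:
            # a perturbation crossed the PD boundary: pull the correlations
            # slightly toward zero and retry
            theta[r0:r0 + 3] *= 0.95
            params = lik.unpack(theta)
            base, D, D2 = lik.index_derivs(params)
        f = float(w @ base)
        g_nat = assemble_gradient(D, X1, X2, w)
        H_nat = assemble_hessian(D2, X1, X2, w)
        rho = params.rho
        jac = 1.0 - rho ** 2
        g = g_nat.copy()
        g[r0:r0 + 3] *= jac
        H = H_nat.copy()
        H[r0:r0 + 3, :] *= jac[:, None]
        H[:, r0:r0 + 3] *= jac[None, :]
        H[r0:r0 + 3, r0:r0 + 3][np.diag_indices(3)] += \
            g_nat[r0:r0 + 3] * (-2.0 * rho * jac)
        info = {"params": params, "base": base, "D": D, "D2": D2,
                "loglik": f, "grad": g, "grad_nat": g_nat}
        if free_mask is not None:
            gf = g[free_mask]
            Af = -H[np.ix_(free_mask, free_mask)]
        else:
            gf = g
            Af = -H
        lam = 0.0
        scale = float(np.abs(np.diag(Af)).max()) or 1.0
        stepf = None
        for _ in range(20):
            try:
                c, low = scipy.linalg.cho_factor(Af + lam * np.eye(len(Af)))
                cand = scipy.linalg.cho_solve((c, low), gf)
                if gf @ cand > 0:
                    stepf = cand
                    break
            except np.linalg.LinAlgError:
                pass
            lam = max(10.0 * lam, 1e-7 * scale)
        if stepf is None:  # pathological curvature: scaled gradient ascent
            stepf = gf / scale
        if free_mask is not None:
            step = np.zeros_like(theta)
            step[free_mask] = stepf
        else:
            step = stepf
        expected = 0.5 * float(g @ step)
        if expected < improve_tol * (1.0 + abs(f)) or \
                np.max(np.abs(step)) < step_tol:
            converged = True
            break
        t = 1.0
        accepted = False
        for _ in range(25):
            f_try = value(theta + t * step)
            if f_try >= f + 1e-4 * t * float(g @ step):
                realized = f_try - f
                theta = theta + t * step
                accepted = True
                break
            t *= 0.5
        if not accepted:  # no ascent step found: treat as converged-in-noise
            converged = True
            break
        # simulation-noise stall: repeated micro-steps with negligible gain
        if t <= 2 ** -8 and realized < 1e-3 * (1.0 + abs(f) * 1e-4):
            stalls += 1
            if stalls >= 2:
                converged = True
                break
        else:
            stalls = 0
    return theta, converged, info


def fit_model(design: DesignMatrices, spec: ModelSpec | None = None, *,
              n_draws: int = 200, seed: int = 0, mode: str = "iid",
              max_iter: int = 40, warm_draws: int = 50,
              fix_rho=None, bic_n: str = "obs") -> FitResult:
    """Fit the selection system by maximum simulated likelihood.

    Weights are normalized to mean one before fitting (a pure rescaling of
    the objective).  Optimization starts from the pilot fits and runs in two
    stages under common random numbers: a warm Newton stage with
    ``warm_draws`` GHK draws gets close cheaply, then the full ``n_draws``
    simulator polishes.  BIC uses the number of observations by default
    (``bic_n="individuals"`` switches to clusters).  Non-convergence is
    flagged on the result, never silently dropped.

    ``fix_rho`` pins the cross-equation correlations at the given values
    instead of estimating them.  With a near-universal selection rate the
    likelihood is almost flat in the correlations, so the free-rho fit has a
    very diffuse rho; fixing rho = 0 recovers the factorized (independent
    two-equation) model exactly.
    """
    _check_groups(design.y1)
    sdesign, s1, s2 = _scaled_design(design)
    b1, b2 = pilot_fits(design)
    lik_full = SelectionLikelihood(sdesign, n_draws=n_draws, seed=seed, mode=mode)
    rho0 = np.zeros(3) if fix_rho is None else np.asarray(fix_rho, dtype=float)
    theta = lik_full.pack(ParameterVector(b1 * s1, b2 * s2, rho0,
                                          IID_OMEGA.copy()))
    free_mask = None
    if fix_rho is not None:
        free_mask = np.ones(len(theta), dtype=bool)
        r0 = lik_full.k1 + 3 * lik_full.k2
        free_mask[r0:r0 + 3] = False
    if mode == "unrestricted":
        # the free Omega coordinates sit outside the index-space machinery;
        # quasi-Newton with plain finite differences handles them
        res = scipy.optimize.minimize(
            lik_full.neg_loglik, theta, jac=lik_full.neg_grad,
            method="L-BFGS-B", options={"maxiter": 10 * max_iter,
                                        "ftol": 1e-11, "maxcor": 30})
        theta, converged = res.x, bool(res.success)
        params_s = lik_full.unpack(theta)
        base, D, D2 = lik_full.index_derivs(params_s)
        info = {"params": params_s, "D": D, "D2": D2,
                "loglik": float(lik_full.w @ base), "grad": -res.jac}
    else:
        if warm_draws and warm_draws < n_draws:
            lik_warm = SelectionLikelihood(sdesign, n_draws=warm_draws,
                                           seed=seed, mode=mode)
            theta, _, _ = _newton_msl(lik_warm, theta, max_iter=max_iter,
                                      free_mask=free_mask)
        theta, converged, info = _newton_msl(lik_full, theta, max_iter=max_iter,
                                             free_mask=free_mask)
        params_s = info["params"]
    params = ParameterVector(params_s.beta1 / s1, params_s.beta2 / s2,
                             params_s.rho, params_s.omega)
    loglik = info["loglik"]
    # the index derivatives at the optimum are scale-free: assemble scores
    # and Hessian against the *natural* design for the sandwich
    w = lik_full.w
    scores = assemble_scores(info["D"], design.X1, design.X2)
    hess = assemble_hessian(info["D2"], design.X1, design.X2, w)
    if fix_rho is not None:
        # rho is known, not estimated: invert only the beta block
        nb = design.X1.shape[1] + 3 * design.X2.shape[1]
        sub = sandwich_vcov(scores[:, :nb], hess[:nb, :nb],
                            design.cluster_ids, w)
        vcov = np.zeros((nb + 3, nb + 3))
        vcov[:nb, :nb] = sub
    else:
        vcov = sandwich_vcov(scores, hess, design.cluster_ids, w)
    k = lik_full.n_free - (3 if fix_rho is not None else 0)
    n_for_bic = design.n_obs if bic_n == "obs" else design.n_individuals
    aic, bic = information_criteria(loglik, k, n_for_bic)
    return FitResult(
        params=params, vcov=vcov, loglik=loglik,
        n_obs=design.n_obs, n_individuals=design.n_individuals,
        converged=bool(converged), n_draws=n_draws, seed=seed, mode=mode,
        aic=aic, bic=bic,
        eq1_names=design.eq1_names, eq2_names=design.eq2_names,
        age_center=design.age_center,
        grad_norm=float(np.abs(info["grad"]).max()),
        pilot={"beta1": b1, "beta2": b2},
        optimizer_message="damped Newton on the simulated likelihood",
    )


def hosmer_lemeshow_refit(design: DesignMatrices, groups: int = 10):
    """HL test on the *unweighted* refit of the selection-equation probit.

    The test statistic is only approximately chi-square under survey weights,
    so it is computed on an unweighted probit refit of equation 1.
    """
    model = sm.GLM(design.y1, design.X1,
                   family=sm.families.Binomial(sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    p = np.clip(np.asarray(res.fittedvalues), 1e-10, 1 - 1e-10)
    return hosmer_lemeshow(design.y1, p, groups=groups)


class SelectionMultinomialProbit(BaseEstimator):
    """Panel multinomial probit with sample selection (scikit-learn style).

    Parameters
    ----------
    spec : ModelSpec or None
        Term lists for the two equations; defaults to the packaged layout.
    n_draws : int
        GHK draws per observation (scrambled antithetic Halton).
    seed : int
        Seed for the common random numbers.
    mode : {"iid", "unrestricted"}
        Whether the differenced-error covariance Omega is pinned to the
        iid structure (default; only the three cross-equation correlations
        are estimated) or its free Cholesky entries are estimated too.
    max_iter : int
        Quasi-Newton iteration cap.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult
    params_ : ParameterVector
    vcov_ : ndarray — cluster-robust covariance of the free parameters
    loglik_, aic_, bic_ : float
    converged_ : bool
    design_ : DesignMatrices — the estimation sample
    """

    def __init__(self, spec: ModelSpec | None = None, n_draws: int = 200,
                 seed: int = 0, mode: str = "iid", max_iter: int = 40,
                 fix_rho=None):
        self.spec = spec
        self.n_draws = n_draws
        self.seed = seed
        self.mode = mode
        self.max_iter = max_iter
        self.fix_rho = fix_rho

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None, sample_weight=None, groups=None):
        """Fit on a covariate frame plus outcomes.

        ``X`` is a DataFrame with the covariate columns; ``y`` is (n, 2)
        array-like or a DataFrame with ``y1``/``y2``; ``sample_weight`` are
        the longitudinal survey weights (default 1); ``groups`` are the
        cluster (person) ids (default: one cluster per row).
        """
        X = pd.DataFrame(X).copy()
        if y is None:
            if not {"y1", "y2"} <= set(X.columns):
                raise ValueError("pass y or include y1/y2 columns in X")
        else:
            yarr = np.asarray(pd.DataFrame(y))
            X["y1"], X["y2"] = yarr[:, 0].astype(int), yarr[:, 1]
        if sample_weight is not None:
            X["weight"] = np.asarray(sample_weight, dtype=float)
        elif "weight" not in X:
            X["weight"] = 1.0
        if groups is not None:
            X["person_id"] = np.asarray(groups)
        elif "person_id" not in X:
            X["person_id"] = np.arange(len(X))
        design = build_design(X, self.spec)
        return self.fit_design(design)

    def fit_design(self, design: DesignMatrices):
        """Fit directly from pre-built design matrices."""
        self.result_ = fit_model(design, self.spec, n_draws=self.n_draws,
                                 seed=self.seed, mode=self.mode,
                                 max_iter=self.max_iter, fix_rho=self.fix_rho)
        self.design_ = design
        self.params_ = self.result_.params
        self.vcov_ = self.result_.vcov
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.converged_ = self.result_.converged
        return self

    # -- prediction --------------------------------------------------------
    def predict_proba(self, X: pd.DataFrame | DesignMatrices) -> np.ndarray:
        """(n, 5) probabilities: non-needs then joint P(needs, alternative j)."""
        from .effects import batch_probabilities  # local import to avoid cycle

        if isinstance(X, DesignMatrices):
            X1, X2 = X.X1, X.X2
        else:
            X = pd.DataFrame(X).copy()
            if "weight" not in X:
                X["weight"] = 1.0
            if "person_id" not in X:
                X["person_id"] = np.arange(len(X))
            if "y1" not in X:
                X["y1"], X["y2"] = 1, 1.0  # outcomes unused for prediction
            spec = self.spec or ModelSpec()
            spec = ModelSpec(eq1_terms=spec.eq1_terms, eq2_terms=spec.eq2_terms,
                             reference_alternative=spec.reference_alternative,
                             age_center=self.result_.age_center)
            d = build_design(X, spec)
            X1, X2 = d.X1, d.X2
        return batch_probabilities(self.params_, X1, X2,
                                   n_draws=self.n_draws, seed=self.seed)

    def predict(self, X) -> np.ndarray:
        """Most probable outcome: 0 = non-needs, 1..4 = alternatives."""
        return np.argmax(self.predict_proba(X), axis=1)

    def summary(self) -> pd.DataFrame:
        return self.result_.summary_frame()
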