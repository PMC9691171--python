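"""GHK simulation core for the two-equation needs-selection model.

Model.  A binary *needs* indicator is driven by a probit selection equation
``y1 = 1(x1'b1 + e1 > 0)`` with ``e1 ~ N(0, 1)``.  Conditional on needs, a
four-alternative multinomial probit picks the outcome (met needs is the
reference alternative, the other three are access barriers): alternative j
is chosen when its latent utility ``x2'b2j + e2j`` is maximal, with
``b2,1 = 0``.  Working in differenced errors ``u_j = e2j - e2,1`` (j=2,3,4),
the joint distribution of ``(e1, u2, u3, u4)`` is multivariate normal with
``Var(e1) = 1``, ``Cov(u) = Omega`` and ``Corr(e1, u_j) = rho_j``.  The scale
normalization fixes ``Omega[0,0] = 2``; in the default "iid mode" Omega is
pinned to the differenced-iid structure (2 on the diagonal, 1 off), which
nests alternative-level iid standard-normal errors and keeps coefficients on
the familiar multinomial-probit scale.

Each choice is a (transformed) orthant of ``(e1, u)``-space, and every
likelihood contribution is a multivariate-normal rectangle probability,
simulated with the Geweke–Hajivassiliou–Keane (GHK) recursive sampler driven
by scrambled Halton uniforms with antithetic pairing.  Draws are generated
once per fit from a seed and reused across parameter evaluations (common
random numbers), so the simulated likelihood is a smooth, deterministic
function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

__all__ = [
    "ParameterVector",
    "ChoiceRegion",
    "IID_OMEGA",
    "halton_uniforms",
    "alternative_region",
    "ghk_mvn_rectangle",
    "choice_probabilities",
    "log_likelihood",
    "SelectionLikelihood",
]

#: differenced covariance of iid standard-normal alternative errors
IID_OMEGA = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]])

_TINY = 1e-300

# rows of M_j acting on u = (u2, u3, u4); region is  M_j u + c_j > 0
_M = {
    1: -np.eye(3),
    2: np.array([[1.0, 0, 0], [1.0, -1.0, 0], [1.0, 0, -1.0]]),
    3: np.array([[0, 1.0, 0], [-1.0, 1.0, 0], [0, 1.0, -1.0]]),
    4: np.array([[0, 0, 1.0], [-1.0, 0, 1.0], [0, -1.0, 1.0]]),
}


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


@dataclass
class ParameterVector:
    """Coefficients and error-structure parameters of the joint model.

    ``beta2`` stacks the three non-reference alternative coefficient vectors
    as rows (j = 2, 3, 4); the reference alternative's coefficients are
    identically zero.  ``rho[j-2] = Corr(e1, u_j)``.
    """

    beta1: np.ndarray
    beta2: np.ndarray  # (3, k2)
    rho: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: IID_OMEGA.copy())

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.atleast_2d(np.asarray(self.beta2, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.beta2.shape[0] != 3 or self.rho.shape != (3,):
            raise ValueError("beta2 must be (3, k2) and rho length 3")
        if abs(self.omega[0, 0] - 2.0) > 1e-10:
            raise ValueError("scale normalization requires Omega[0,0] = 2")

    def joint_cov(self) -> np.ndarray:
        """4x4 covariance of (e1, u2, u3, u4); raises if not PD."""
        s = np.sqrt(np.diag(self.omega))
        sigma = np.empty((4, 4))
        sigma[0, 0] = 1.0
        sigma[0, 1:] = sigma[1:, 0] = self.rho * s
        sigma[1:, 1:] = self.omega
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                "joint covariance of (e1, u) is not positive definite") from exc
        return sigma

    def to_frame(self, eq1_names=None, eq2_names=None) -> pd.DataFrame:
        """Flat (name, value) table; serializable and resumable."""
        k1, k2 = len(self.beta1), self.beta2.shape[1]
        eq1 = eq1_names or [f"x{j}" for j in range(k1)]
        eq2 = eq2_names or [f"x{j}" for j in range(k2)]
        rows = [(f"eq1:{t}", v) for t, v in zip(eq1, self.beta1)]
        for j, lab in enumerate(("financial", "time", "lack")):
            rows += [(f"{lab}:{t}", v) for t, v in zip(eq2, self.beta2[j])]
        rows += [(f"rho:{lab}", v) for lab, v in
                 zip(("financial", "time", "lack"), self.rho)]
        tri = np.tril_indices(3)
        rows += [(f"omega:{a+1}{b+1}", self.omega[a, b]) for a, b in zip(*tri)]
        return pd.DataFrame(rows, columns=["name", "value"])

    def to_text(self, path, eq1_names=None, eq2_names=None) -> None:
        self.to_frame(eq1_names, eq2_names).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_text(cls, path) -> "ParameterVector":
        tab = pd.read_csv(path, sep="\t")
        vals = dict(zip(tab["name"], tab["value"]))
        b1 = [v for n, v in vals.items() if n.startswith("eq1:")]
        b2 = [[v for n, v in vals.items() if n.startswith(f"{lab}:")]
              for lab in ("financial", "time", "lack")]
        rho = [vals[f"rho:{lab}"] for lab in ("financial", "time", "lack")]
        omega = np.empty((3, 3))
        for a in range(3):
            for b in range(a + 1):
                omega[a, b] = omega[b, a] = vals[f"omega:{a+1}{b+1}"]
        return cls(np.array(b1), np.array(b2), np.array(rho), omega)


@dataclass
class ChoiceRegion:
    """Alternative ``j`` is chosen iff ``M @ u + c > 0`` componentwise."""

    alternative: int
    M: np.ndarray
    c: np.ndarray


def alternative_region(j: int, beta2: np.ndarray, x2: np.ndarray) -> ChoiceRegion:
    """Choice region of alternative ``j`` in differenced-error space."""
    if j not in (1, 2, 3, 4):
        raise ValueError("alternative must be in {1,2,3,4}")
    eta = np.atleast_2d(beta2) @ np.asarray(x2, dtype=float)  # (eta2, eta3, eta4)
    if j == 1:
        c = -eta
    else:
        i = j - 2
        c = np.array([eta[i], *(eta[i] - np.delete(eta, i))])
    return ChoiceRegion(alternative=j, M=_M[j].copy(), c=c)


def halton_uniforms(n_draws: int, dim: int, seed: int) -> np.ndarray:
    """Scrambled Halton uniforms with antithetic pairing, shape (n_draws, dim)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    half = max(1, n_draws // 2)
    h = qmc.Halton(d=dim, scramble=True, seed=int(seed)).random(half)
    u = np.vstack([h, 1.0 - h])[:n_draws]
    return np.clip(u, 1e-12, 1 - 1e-12)


def _ghk_lower(lower: np.ndarray, chol: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Batch GHK for lower-orthant probabilities P(z > lower), z ~ N(0, L L').

    ``lower`` is (n, d); ``u`` holds uniform draws, either (R, >= d-1)
    shared across rows or (n, R, >= d-1) per observation; returns the (n,)
    vector of probability estimates.
    """
    n, d = lower.shape
    R = u.shape[-2]
    prob = np.ones((n, R))
    z = []
    for k in range(d):
        mu = 0.0
        for m in range(k):
            mu = mu + chol[k, m] * z[m]
        a = (lower[:, k][:, None] - mu) / chol[k, k]
        t = ndtr(-a)  # P(std normal > a)
        prob *= t
        if k < d - 1:
            uk = u[..., k] if u.ndim == 3 else u[:, k][None, :]
            s = np.maximum(t * uk, _TINY)
            z.append(-ndtri(s))  # draw from the upper tail (a, inf)
    return prob.mean(axis=1)


def ghk_mvn_rectangle(lower, upper, cov, n_draws: int = 500, seed: int = 0) -> float:
    """GHK estimate of P(lower < z < upper) for z ~ N(0, cov).

    Bounds may be ``+-inf`` per coordinate.  Deterministic given
    ``(seed, n_draws)``; uses scrambled antithetic Halton uniforms.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = len(lower)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("covariance is not positive definite") from exc
    if d == 1:  # degenerate path: exact normal probability
        s = chol[0, 0]
        return float(ndtr(upper[0] / s) - ndtr(lower[0] / s))
    u = halton_uniforms(n_draws, d, seed)
    prob = np.ones(u.shape[0])
    z = []
    for k in range(d):
        mu = 0.0
        for m in range(k):
            mu = mu + chol[k, m] * z[m]
        a = (lower[k] - mu) / chol[k, k]
        b = (upper[k] - mu) / chol[k, k]
        pa, pb = ndtr(a), ndtr(b)
        t = np.maximum(pb - pa, 0.0)
        prob *= t
        if k < d - 1:
            q = np.clip(pa + t * u[:, k], _TINY, 1 - 1e-16)
            z.append(ndtri(q))
    return float(np.clip(prob.mean(), 0.0, 1.0))


def _region_lower(j: int, Eta2: np.ndarray) -> np.ndarray:
    """Lower bounds (n, 3) on v = M_j u for choice region j; Eta2 is (n, 3)."""
    if j == 1:
        return Eta2.copy()
    i = j - 2
    own = Eta2[:, i]
    others = np.delete(Eta2, i, axis=1)
    return np.column_stack([-own, others[:, 0] - own, others[:, 1] - own])


def _joint_chol(j: int, sigma: np.ndarray) -> np.ndarray:
    """Cholesky of Cov((e1, M_j u)) under joint covariance ``sigma``."""
    T = np.zeros((4, 4))
    T[0, 0] = 1.0
    T[1:, 1:] = _M[j]
    C = T @ sigma @ T.T
    return np.linalg.cholesky(C)


def choice_probabilities(params: ParameterVector, x1, x2,
                         n_draws: int = 500, seed: int = 0):
    """Non-needs and joint needs/alternative probabilities for one covariate row.

    Returns ``(p_nonneeds, p_joint)`` where ``p_joint[j-1] =
    P(y1 = 1, y2 = j)``; the five probabilities sum to one up to GHK noise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    eta1 = float(params.beta1 @ x1)
    Eta2 = (params.beta2 @ x2)[None, :]
    sigma = params.joint_cov()
    u = halton_uniforms(n_draws, 4, seed)
    p_joint = np.empty(4)
    for j in (1, 2, 3, 4):
        lower = np.column_stack([[-eta1], _region_lower(j, Eta2)])
        p_joint[j - 1] = _ghk_lower(lower, _joint_chol(j, sigma), u)[0]
    return float(ndtr(-eta1)), p_joint


class SelectionLikelihood:
    """Weighted simulated log-likelihood of the selection system on a dataset.

    Observations are grouped by outcome (non-needs, met, and the three
    barriers); within a group all rectangle problems share one Cholesky
    factor, so the GHK recursion is vectorized over observations.  First and
    second derivatives are taken by central finite differences in *index
    space* -- the linear indices ``x1'b1``, ``x2'b2j`` and the correlations,
    seven scalars in iid mode -- and chained through the design matrices,
    which keeps a gradient at a handful of likelihood evaluations.
    """

    #: optimizer-space transform: correlations ride through atanh
    def __init__(self, design, n_draws: int = 200, seed: int = 0,
                 mode: str = "iid", p_floor: float = 1e-12):
        if mode not in ("iid", "unrestricted"):
            raise ValueError("mode must be 'iid' or 'unrestricted'")
        self.design = design
        self.n_draws = int(n_draws)
        self.seed = int(seed)
        self.mode = mode
        self.p_floor = float(p_floor)
        self.n_floored = 0
        y1, y2 = design.y1, design.y2
        self.k1 = design.X1.shape[1]
        self.k2 = design.X2.shape[1]
        self.n = len(y1)
        self.idx0 = np.flatnonzero(y1 == 0)
        self.idxj = {j: np.flatnonzero((y1 == 1) & (y2 == j)) for j in (1, 2, 3, 4)}
        if len(self.idx0) + sum(len(v) for v in self.idxj.values()) != self.n:
            raise ValueError("outcomes contain rows that are neither coded "
                             "non-needs nor one of the four alternatives")
        self.w = design.weights / design.weights.mean()
        # per-observation scrambled-Halton draws with antithetic pairing:
        # simulation error then averages out across observations instead of
        # acting as a common distortion of the likelihood surface
        self.u_group = {}
        for j, idx in self.idxj.items():
            if idx.size:
                self.u_group[j] = self._obs_draws(len(idx), j)

    def _obs_draws(self, n_obs: int, tag: int) -> np.ndarray:
        half = max(1, self.n_draws // 2)
        rng = np.random.default_rng([self.seed, tag])
        h = qmc.Halton(d=3, scramble=True, seed=rng).random(n_obs * half)
        h = h.reshape(n_obs, half, 3)
        u = np.concatenate([h, 1.0 - h], axis=1)[:, :self.n_draws]
        return np.clip(u, 1e-12, 1 - 1e-12)

    # -- parameter packing -------------------------------------------------
    @property
    def n_free(self) -> int:
        base = self.k1 + 3 * self.k2 + 3
        return base + (5 if self.mode == "unrestricted" else 0)

    def pack(self, params: ParameterVector) -> np.ndarray:
        parts = [params.beta1, params.beta2.ravel(), np.arctanh(params.rho)]
        if self.mode == "unrestricted":
            L = np.linalg.cholesky(params.omega)
            parts.append(np.array([L[1, 0], np.log(L[1, 1]),
                                   L[2, 0], L[2, 1], np.log(L[2, 2])]))
        return np.concatenate(parts)

    def unpack(self, theta: np.ndarray) -> ParameterVector:
        k1, k2 = self.k1, self.k2
        b1 = theta[:k1]
        b2 = theta[k1:k1 + 3 * k2].reshape(3, k2)
        rho = np.tanh(theta[k1 + 3 * k2:k1 + 3 * k2 + 3])
        omega = IID_OMEGA.copy()
        if self.mode == "unrestricted":
            v = theta[k1 + 3 * k2 + 3:]
            L = np.array([[np.sqrt(2.0), 0, 0],
                          [v[0], np.exp(v[1]), 0],
                          [v[2], v[3], np.exp(v[4])]])
            omega = L @ L.T
        return ParameterVector(b1, b2, rho, omega)

    # -- core index-space likelihood ---------------------------------------
    def _logp_indices(self, eta1, Eta2, rho, omega):
        sigma_ok = True
        s = np.sqrt(np.diag(omega))
        sigma = np.empty((4, 4))
        sigma[0, 0] = 1.0
        sigma[0, 1:] = sigma[1:, 0] = rho * s
        sigma[1:, 1:] = omega
        logp = np.empty(self.n)
        i0 = self.idx0
        logp[i0] = np.log(np.maximum(ndtr(-eta1[i0]), _TINY))
        for j in (1, 2, 3, 4):
            idx = self.idxj[j]
            if idx.size == 0:
                continue
            chol = _joint_chol(j, sigma)  # raises if not PD
            lower = np.column_stack([-eta1[idx], _region_lower(j, Eta2[idx])])
            p = _ghk_lower(lower, chol, self.u_group[j])
            floored = p < self.p_floor
            self.n_floored += int(floored.sum())
            logp[idx] = np.log(np.maximum(p, self.p_floor))
        return logp

    def _indices(self, params: ParameterVector):
        return self.design.X1 @ params.beta1, self.design.X2 @ params.beta2.T

    def logp_obs(self, params: ParameterVector) -> np.ndarray:
        eta1, Eta2 = self._indices(params)
        return self._logp_indices(eta1, Eta2, params.rho, params.omega)

    def value(self, params: ParameterVector) -> float:
        return float(self.w @ self.logp_obs(params))

    # -- derivatives -------------------------------------------------------
    # The seven index-space variables are eta1, eta2..4, rho2..4.  The eta
    # directions are smooth at any scale, but along the correlations the
    # simulated surface carries micro-scale wiggles (observations with tiny
    # conditional probabilities have enormous higher log-derivatives), so
    # rho derivatives are measured at a deliberately larger step -- the
    # macro curvature is what matters for both the Newton step and the
    # variance, and the surface is nearly quadratic in rho at that scale.
    _N_IDX = 7

    H_ETA = 1e-5       # first differences, linear indices
    H_ETA2 = 3e-4      # second differences, linear indices
    H_RHO = 0.05       # first and second differences, correlations

    def _perturbed(self, eta1, Eta2, rho, omega, a: int, h: float):
        if a == 0:
            return self._logp_indices(eta1 + h, Eta2, rho, omega)
        if a < 4:
            E = Eta2.copy()
            E[:, a - 1] += h
            return self._logp_indices(eta1, E, rho, omega)
        r = rho.copy()
        r[a - 4] += h
        return self._logp_indices(eta1, Eta2, r, omega)

    def _rho_step(self, rho, omega, h: float) -> float:
        """Cap the rho FD step so perturbed covariances stay PD (a rho shift
        of d moves eigenvalues by at most ~2 d on the iid scale)."""
        s = np.sqrt(np.diag(omega))
        sigma = np.empty((4, 4))
        sigma[0, 0] = 1.0
        sigma[0, 1:] = sigma[1:, 0] = rho * s
        sigma[1:, 1:] = omega
        lam_min = float(np.linalg.eigvalsh(sigma).min())
        return float(min(h, max(1e-4, (lam_min - 1e-5) / 4.0)))

    def _steps(self, rho, omega, h_eta, h_rho):
        hr = self._rho_step(rho, omega, h_rho)
        return np.array([h_eta] * 4 + [hr] * 3)

    def index_grads(self, params: ParameterVector, h: float | None = None):
        """Per-observation d log p / d(indices); (n, 7) array, plus base logp."""
        eta1, Eta2 = self._indices(params)
        rho, omega = params.rho, params.omega
        hs = self._steps(rho, omega, h or self.H_ETA, self.H_RHO)
        base = self._logp_indices(eta1, Eta2, rho, omega)
        D = np.empty((self.n, self._N_IDX))
        for a in range(self._N_IDX):
            fp = self._perturbed(eta1, Eta2, rho, omega, a, hs[a])
            fm = self._perturbed(eta1, Eta2, rho, omega, a, -hs[a])
            D[:, a] = (fp - fm) / (2 * hs[a])
        return base, D

    def scores(self, params: ParameterVector, h: float = 1e-5) -> np.ndarray:
        """Per-observation score of log p w.r.t. the natural free parameters
        (beta1, beta2 rows, rho); unweighted. Shape (n, n_free_natural)."""
        _, D = self.index_grads(params, h)
        return assemble_scores(D, self.design.X1, self.design.X2)

    def index_derivs(self, params: ParameterVector, h: float | None = None):
        """Base log p, per-obs first and second index-space derivatives.

        One combined pass: the +-h single perturbations feed both the central
        first differences and the Hessian diagonal; four-point differences
        fill the off-diagonal pairs.  Returns ``(base, D, D2)`` with shapes
        (n,), (n, 7), (n, 7, 7).
        """
        eta1, Eta2 = self._indices(params)
        rho, omega = params.rho, params.omega
        hs = self._steps(rho, omega, h or self.H_ETA2, self.H_RHO)
        base = self._logp_indices(eta1, Eta2, rho, omega)
        m = self._N_IDX
        fp = [self._perturbed(eta1, Eta2, rho, omega, a, hs[a]) for a in range(m)]
        fm = [self._perturbed(eta1, Eta2, rho, omega, a, -hs[a]) for a in range(m)]
        D = np.empty((self.n, m))
        D2 = np.empty((self.n, m, m))
        for a in range(m):
            D[:, a] = (fp[a] - fm[a]) / (2 * hs[a])
            D2[:, a, a] = (fp[a] - 2 * base + fm[a]) / hs[a] ** 2

        def shifted(a, b, sa, sb):
            e1, E, r = eta1, Eta2, rho
            for v, s in ((a, sa), (b, sb)):
                if v == 0:
                    e1 = e1 + s * hs[v]
                elif v < 4:
                    E = E.copy()
                    E[:, v - 1] += s * hs[v]
                else:
                    r = r.copy()
                    r[v - 4] += s * hs[v]
            return self._logp_indices(e1, E, r, omega)

        for a in range(m):
            for b in range(a + 1, m):
                d2 = (shifted(a, b, 1, 1) - shifted(a, b, 1, -1)
                      - shifted(a, b, -1, 1) + shifted(a, b, -1, -1)) \
                    / (4 * hs[a] * hs[b])
                D2[:, a, b] = D2[:, b, a] = d2
        return base, D, D2

    def hessian(self, params: ParameterVector, h: float | None = None) -> np.ndarray:
        """Weighted Hessian of the log-likelihood w.r.t. natural parameters."""
        _, _, D2 = self.index_derivs(params, h)
        return assemble_hessian(D2, self.design.X1, self.design.X2, self.w)

    # -- optimizer interface (packed space, tanh correlations) -------------
    def neg_loglik(self, theta: np.ndarray) -> float:
        params = self.unpack(theta)
        try:
            return -float(self.w @ self.logp_obs(params))
        except np.linalg.LinAlgError:
            a = theta[self.k1 + 3 * self.k2:self.k1 + 3 * self.k2 + 3]
            return 1e10 * (1.0 + float(a @ a))

    def neg_grad(self, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
        params = self.unpack(theta)
        g = np.zeros_like(theta)
        r0 = self.k1 + 3 * self.k2
        try:
            _, D = self.index_grads(params, h)
        except np.linalg.LinAlgError:
            g[r0:r0 + 3] = 2e10 * theta[r0:r0 + 3]
            return g
        X1, X2 = self.design.X1, self.design.X2
        wD = self.w[:, None] * D
        g[:self.k1] = X1.T @ wD[:, 0]
        for j in range(3):
            g[self.k1 + j * self.k2:self.k1 + (j + 1) * self.k2] = X2.T @ wD[:, 1 + j]
        # chain atanh(rho): d rho / d a = 1 - rho^2
        g[r0:r0 + 3] = wD[:, 4:7].sum(axis=0) * (1.0 - params.rho ** 2)
        if self.mode == "unrestricted":
            # omega entries move many things at once; plain FD on the 5 free
            # Cholesky coordinates (cheap relative to the rest of the fit)
            f0 = -self.neg_loglik(theta)
            for i in range(5):
                tp = theta.copy()
                tp[r0 + 3 + i] += 1e-5
                g[r0 + 3 + i] = (-self.neg_loglik(tp) - f0) / 1e-5
        return -g


def assemble_gradient(D: np.ndarray, X1: np.ndarray, X2: np.ndarray,
                      w: np.ndarray) -> np.ndarray:
    """Chain per-obs index derivatives into the natural-parameter gradient."""
    k1, k2 = X1.shape[1], X2.shape[1]
    g = np.empty(k1 + 3 * k2 + 3)
    wD = w[:, None] * D
    g[:k1] = X1.T @ wD[:, 0]
    for j in range(3):
        g[k1 + j * k2:k1 + (j + 1) * k2] = X2.T @ wD[:, 1 + j]
    g[k1 + 3 * k2:] = wD[:, 4:7].sum(axis=0)
    return g


def assemble_scores(D: np.ndarray, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Per-observation natural-parameter scores from index derivatives."""
    cols = [D[:, [0]] * X1]
    for j in range(3):
        cols.append(D[:, [1 + j]] * X2)
    cols.append(D[:, 4:7])
    return np.hstack(cols)


def assemble_hessian(D2: np.ndarray, X1: np.ndarray, X2: np.ndarray,
                     w: np.ndarray) -> np.ndarray:
    """Chain per-obs second index derivatives into the full Hessian."""
    k1, k2 = X1.shape[1], X2.shape[1]
    mats = [X1] + [X2] * 3  # index 0..3 -> matrix; 4..6 -> rho scalars
    sizes = [k1] + [k2] * 3 + [1] * 3
    offs = np.concatenate([[0], np.cumsum(sizes)])
    p = offs[-1]
    H = np.zeros((p, p))
    for a in range(7):
        for b in range(a, 7):
            W = w * D2[:, a, b]
            if a < 4 and b < 4:
                blk = mats[a].T @ (W[:, None] * mats[b])
            elif a < 4:
                blk = (mats[a].T @ W)[:, None]
            else:
                blk = np.array([[W.sum()]])
            H[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = blk
            if b != a:
                H[offs[b]:offs[b + 1], offs[a]:offs[a + 1]] = blk.T
    return H


def log_likelihood(params: ParameterVector, design, n_draws: int = 200,
                   seed: int = 0):
    """Weighted simulated log-likelihood and per-observation contributions.

    Weights are used as given (no normalization here), so doubling every
    weight exactly doubles the total.  Deterministic given ``seed``.
    """
    lik = SelectionLikelihood(design, n_draws=n_draws, seed=seed)
    logp = lik.logp_obs(params)
    contrib = design.weights * logp
    return float(contrib.sum()), contrib
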