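"""Average adjusted probabilities (AAP) across an age grid by gender.

For each grid point (gender g, age a), every observation in the estimation
sample has its gender and age — and *all* terms derived from them: the
centered age, its square, and the gender interactions — overwritten with
(g, a), while all other covariates stay at their observed values.  The
weighted average of the resulting predicted probabilities is the AAP:
the probability of experiencing healthcare needs, and (by default) the
joint probability of having needs *and* ending with a particular barrier.
A conditional-on-needs variant divides each observation's joint barrier
probability by its needs probability before averaging.

95% confidence bands come from the delta method: the numerical Jacobian of
each AAP with respect to the free parameters (taken in index space and
chained through the design matrices) times the cluster-robust covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .design import ModelSpec, build_design
from .ghk import ParameterVector, _ghk_lower, _joint_chol, _region_lower, halton_uniforms

__all__ = ["batch_probabilities", "average_adjusted_probability",
           "plot_needs_aap", "plot_barrier_aap"]

_BARRIERS = {"financial": 2, "time": 3, "lack": 4}


def batch_probabilities(params: ParameterVector, X1, X2,
                        n_draws: int = 200, seed: int = 0) -> np.ndarray:
    """(n, 5) matrix [P(y1=0), P(y1=1, y2=j) for j=1..4] row by row."""
    u = halton_uniforms(n_draws, 4, seed)
    sigma = params.joint_cov()
    eta1 = np.asarray(X1) @ params.beta1
    Eta2 = np.asarray(X2) @ params.beta2.T
    out = np.empty((len(eta1), 5))
    out[:, 0] = ndtr(-eta1)
    for j in (1, 2, 3, 4):
        lower = np.column_stack([-eta1, _region_lower(j, Eta2)])
        out[:, j] = _ghk_lower(lower, _joint_chol(j, sigma), u)
    return out


def _joint_p_indices(eta1, Eta2, rho, omega, j, u):
    s = np.sqrt(np.diag(omega))
    sigma = np.empty((4, 4))
    sigma[0, 0] = 1.0
    sigma[0, 1:] = sigma[1:, 0] = rho * s
    sigma[1:, 1:] = omega
    lower = np.column_stack([-eta1, _region_lower(j, Eta2)])
    return _ghk_lower(lower, _joint_chol(j, sigma), u)


def _perturb(eta1, Eta2, rho, a, h):
    if a == 0:
        return eta1 + h, Eta2, rho
    if a < 4:
        E = Eta2.copy()
        E[:, a - 1] += h
        return eta1, E, rho
    r = rho.copy()
    r[a - 4] += h
    return eta1, Eta2, r


def _grid_design(coded: pd.DataFrame, spec: ModelSpec, gender: int, age: float):
    mod = coded.copy()
    mod["man"] = gender
    mod["age"] = float(age)
    d = build_design(mod, spec, check_degenerate=False)
    return d.X1, d.X2


def average_adjusted_probability(fit, coded: pd.DataFrame, *,
                                 ages=None, genders=(1, 0), kind: str = "joint",
                                 level: float = 0.95, ci: bool = True,
                                 n_draws: int | None = None,
                                 seed: int | None = None,
                                 age_range=(18.0, 100.0),
                                 fd_step: float = 1e-5) -> pd.DataFrame:
    """AAP grid with optional delta-method confidence bands.

    Parameters
    ----------
    fit : FitResult (or fitted :class:`~needsel.model.SelectionMultinomialProbit`,
        whose ``result_`` is used) on the estimation sample.
    coded : the coded estimation sample (covariates + weights), whose
        observed non-age, non-gender covariates are held fixed.
    kind : "joint" reports P(needs & barrier); "conditional" reports
        P(barrier | needs), averaged over observations.

    Returns a tidy frame indexed by (gender, age) with columns ``p_needs``,
    ``p_unmet``, ``p_financial``, ``p_time``, ``p_lack`` and, when ``ci``,
    ``*_lo``/``*_hi`` bounds.
    """
    if hasattr(fit, "result_"):
        fit = fit.result_
    if kind not in ("joint", "conditional"):
        raise ValueError("kind must be 'joint' or 'conditional'")
    ages = list(ages) if ages is not None else list(range(20, 91, 5))
    for a in ages:
        if not (age_range[0] <= a <= age_range[1]):
            import warnings
            warnings.warn(f"grid age {a} outside plausible range {age_range}")
    n_draws = n_draws or fit.n_draws
    seed = fit.seed if seed is None else seed
    u = halton_uniforms(n_draws, 4, seed)
    spec = ModelSpec(eq1_terms=fit.eq1_names, eq2_terms=fit.eq2_names,
                     age_center=fit.age_center)
    params, vcov = fit.params, fit.vcov
    rho, omega = params.rho, params.omega
    w = coded["weight"].to_numpy(dtype=float)
    w = w / w.sum()
    k1, k2 = len(fit.eq1_names), len(fit.eq2_names)
    zq = norm.ppf(0.5 + level / 2.0)

    def chain(X1, X2, d_idx):
        """Map mean index-derivatives (7,) pattern to free-parameter gradient."""
        g = np.empty(k1 + 3 * k2 + 3)
        g[:k1] = X1.T @ (w * d_idx[:, 0])
        for j in range(3):
            g[k1 + j * k2:k1 + (j + 1) * k2] = X2.T @ (w * d_idx[:, 1 + j])
        g[k1 + 3 * k2:] = (w[:, None] * d_idx[:, 4:7]).sum(axis=0)
        return g

    rows = []
    for g_val in genders:
        for a_val in ages:
            X1, X2 = _grid_design(coded, spec, g_val, a_val)
            eta1 = X1 @ params.beta1
            Eta2 = X2 @ params.beta2.T
            p_needs_obs = ndtr(eta1)
            row = {"gender": g_val, "age": a_val,
                   "p_needs": float(w @ p_needs_obs)}
            pj = {}
            for lab, j in _BARRIERS.items():
                joint = _joint_p_indices(eta1, Eta2, rho, omega, j, u)
                pj[lab] = joint / p_needs_obs if kind == "conditional" else joint
                row[f"p_{lab}"] = float(w @ pj[lab])
            row["p_unmet"] = row["p_financial"] + row["p_time"] + row["p_lack"]

            if ci:
                # needs AAP depends on beta1 only; analytic gradient
                gn = np.zeros(k1 + 3 * k2 + 3)
                gn[:k1] = X1.T @ (w * norm.pdf(eta1))
                row["p_needs_lo"] = row["p_needs"] - zq * np.sqrt(gn @ vcov @ gn)
                row["p_needs_hi"] = row["p_needs"] + zq * np.sqrt(gn @ vcov @ gn)
                D = {lab: np.empty((len(eta1), 7)) for lab in _BARRIERS}
                for a_idx in range(7):
                    e1p, E2p, rp = _perturb(eta1, Eta2, rho, a_idx, fd_step)
                    e1m, E2m, rm = _perturb(eta1, Eta2, rho, a_idx, -fd_step)
                    for lab, j in _BARRIERS.items():
                        pp = _joint_p_indices(e1p, E2p, rp, omega, j, u)
                        pm = _joint_p_indices(e1m, E2m, rm, omega, j, u)
                        if kind == "conditional":
                            pp = pp / ndtr(e1p)
                            pm = pm / ndtr(e1m)
                        D[lab][:, a_idx] = (pp - pm) / (2 * fd_step)
                g_unmet = np.zeros(k1 + 3 * k2 + 3)
                for lab in _BARRIERS:
                    gl = chain(X1, X2, D[lab])
                    g_unmet += gl
                    se = np.sqrt(max(gl @ vcov @ gl, 0.0))
                    row[f"p_{lab}_lo"] = row[f"p_{lab}"] - zq * se
                    row[f"p_{lab}_hi"] = row[f"p_{lab}"] + zq * se
                se = np.sqrt(max(g_unmet @ vcov @ g_unmet, 0.0))
                row["p_unmet_lo"] = row["p_unmet"] - zq * se
                row["p_unmet_hi"] = row["p_unmet"] + zq * se
                for key in list(row):
                    if key.endswith(("_lo", "_hi")):
                        row[key] = float(np.clip(row[key], 0.0, 1.0))
            rows.append(row)
    return pd.DataFrame(rows)


def _gender_label(g: int) -> str:
    return "men" if g == 1 else "women"


def plot_needs_aap(grid: pd.DataFrame, ax=None):
    """Needs-AAP trajectories by gender with confidence bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for g_val, sub in grid.groupby("gender"):
        sub = sub.sort_values("age")
        ax.plot(sub["age"], sub["p_needs"], marker="o", label=_gender_label(g_val))
        if "p_needs_lo" in sub:
            ax.fill_between(sub["age"], sub["p_needs_lo"], sub["p_needs_hi"], alpha=0.2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("AAP of experiencing healthcare needs")
    ax.legend()
    return ax.figure


def plot_barrier_aap(grid: pd.DataFrame):
    """Per-gender panels with the three barrier-AAP curves."""
    import matplotlib.pyplot as plt

    genders = sorted(grid["gender"].unique(), reverse=True)
    fig, axes = plt.subplots(1, len(genders), figsize=(11, 4.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, g_val in zip(axes, genders):
        sub = grid[grid["gender"] == g_val].sort_values("age")
        for lab in _BARRIERS:
            ax.plot(sub["age"], sub[f"p_{lab}"], marker=".", label=lab)
            if f"p_{lab}_lo" in sub:
                ax.fill_between(sub["age"], sub[f"p_{lab}_lo"], sub[f"p_{lab}_hi"],
                                alpha=0.15)
        ax.set_title(_gender_label(g_val))
        ax.set_xlabel("age (years)")
    axes[0].set_ylabel("AAP of each barrier to healthcare")
    axes[0].legend()
    fig.tight_layout()
    return fig
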