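import numpy as np
import pandas as pd
import pytest

from needsel.design import ModelSpec, build_design
from needsel.effects import (average_adjusted_probability, batch_probabilities,
                             plot_barrier_aap, plot_needs_aap)
from needsel.ghk import ParameterVector
from needsel.model import FitResult
from scipy.special import ndtr


def synthetic_fit(eq1_terms, eq2_terms, beta1, beta2, rho=(0.2, 0.2, 0.2),
                  age_center=52.0, n_draws=120, seed=5):
    """Hand-assembled FitResult (synthetic stand-in, no estimation)."""
    pv = ParameterVector(np.asarray(beta1, float), np.asarray(beta2, float),
                         np.asarray(rho, float))
    k = len(beta1) + 3 * len(eq2_terms) + 3
    return FitResult(params=pv, vcov=np.eye(k) * 1e-4, loglik=0.0,
                     n_obs=0, n_individuals=0, converged=True,
                     n_draws=n_draws, seed=seed, mode="iid", aic=0.0, bic=0.0,
                     eq1_names=list(eq1_terms), eq2_names=list(eq2_terms),
                     age_center=age_center)


def test_intercept_only_model_gives_flat_grid(small_coded):
    fit = synthetic_fit(["const"], ["const"], [0.8],
                        [[-1.5], [-1.2], [-2.0]], rho=(0.0, 0.0, 0.0))
    grid = average_adjusted_probability(fit, small_coded, ages=[20, 55, 90],
                                        ci=False)
    assert np.allclose(grid["p_needs"], ndtr(0.8), atol=1e-12)
    for col in ("p_needs", "p_financial", "p_time", "p_lack"):
        assert grid[col].nunique() == 1  # no covariate dependence at all


def test_no_age_terms_model_is_flat_in_age(small_coded):
    fit = synthetic_fit(["const", "man"], ["const", "man"],
                        [0.5, -0.4],
                        [[-1.0, 0.2], [-1.5, 0.1], [-2.0, -0.3]])
    grid = average_adjusted_probability(fit, small_coded,
                                        ages=[20, 50, 90], ci=False)
    for g_val, sub in grid.groupby("gender"):
        for col in ("p_needs", "p_unmet", "p_financial"):
            assert sub[col].nunique() == 1
    men = grid[grid.gender == 1]["p_needs"].iloc[0]
    women = grid[grid.gender == 0]["p_needs"].iloc[0]
    assert men == pytest.approx(ndtr(0.1)) and women == pytest.approx(ndtr(0.5))


def test_grid_matches_brute_force_recomputation(small_fit, small_coded):
    grid = average_adjusted_probability(small_fit, small_coded,
                                        ages=[25, 60], ci=False)
    spec = ModelSpec(eq1_terms=small_fit.eq1_names,
                     eq2_terms=small_fit.eq2_names,
                     age_center=small_fit.age_center)
    w = small_coded["weight"].to_numpy()
    w = w / w.sum()
    for _, row in grid.iterrows():
        mod = small_coded.copy()
        mod["man"], mod["age"] = row["gender"], float(row["age"])
        d = build_design(mod, spec, check_degenerate=False)
        P = batch_probabilities(small_fit.params, d.X1, d.X2,
                                small_fit.n_draws, small_fit.seed)
        assert row["p_needs"] == pytest.approx(w @ ndtr(d.X1 @ small_fit.params.beta1), abs=1e-12)
        assert row["p_financial"] == pytest.approx(w @ P[:, 2], abs=1e-6)
        assert row["p_time"] == pytest.approx(w @ P[:, 3], abs=1e-6)
        assert row["p_lack"] == pytest.approx(w @ P[:, 4], abs=1e-6)


def test_barrier_probabilities_add_up_and_cis_bracket(small_fit, small_coded):
    grid = average_adjusted_probability(small_fit, small_coded,
                                        ages=[30, 70], ci=True)
    assert np.allclose(grid["p_unmet"],
                       grid[["p_financial", "p_time", "p_lack"]].sum(axis=1))
    for col in ("p_needs", "p_unmet", "p_financial", "p_time", "p_lack"):
        assert ((grid[f"{col}_lo"] <= grid[col] + 1e-12)
                & (grid[col] <= grid[f"{col}_hi"] + 1e-12)).all()
        assert (grid[f"{col}_lo"] >= 0).all() and (grid[f"{col}_hi"] <= 1).all()


def test_conditional_mode_dominates_joint(small_fit, small_coded):
    joint = average_adjusted_probability(small_fit, small_coded,
                                         ages=[40], ci=False)
    cond = average_adjusted_probability(small_fit, small_coded, ages=[40],
                                        kind="conditional", ci=False)
    for col in ("p_financial", "p_time", "p_lack"):
        assert (cond[col] >= joint[col] - 1e-12).all()
    with pytest.raises(ValueError):
        average_adjusted_probability(small_fit, small_coded, kind="marginal")


def test_grid_is_deterministic(small_fit, small_coded):
    a = average_adjusted_probability(small_fit, small_coded, ages=[35], ci=True)
    b = average_adjusted_probability(small_fit, small_coded, ages=[35], ci=True)
    pd.testing.assert_frame_equal(a, b)


def test_out_of_range_age_warns(small_fit, small_coded):
    with pytest.warns(UserWarning, match="plausible range"):
        average_adjusted_probability(small_fit, small_coded, ages=[150],
                                     ci=False)


def test_figures_render(small_fit, small_coded):
    grid = average_adjusted_probability(small_fit, small_coded,
                                        ages=[20, 50, 90], ci=True)
    fig1 = plot_needs_aap(grid)
    fig2 = plot_barrier_aap(grid)
    assert fig1.axes and len(fig2.axes) == 2
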