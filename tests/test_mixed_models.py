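"""Estimation core: REML behaviour, Henderson/ridge equivalence, prediction
contracts and G-BLUP shrinkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from megs import Grm
from megs.mixed_models import (
    FixedCoder,
    estimate_asv_variance,
    fit_gblup_genotype,
    fit_two_component,
    predict,
    reml_single_component,
)


def _ridge_oracle(y, X, Z, M, s_a, s_g, s_e):
    """Dense closed-form generalized ridge on the concatenated design.

    Minimizes ||y - Xb - Zu - Mv||^2 + (s_e/s_a)||u||^2 + (s_e/s_g)||v||^2,
    the textbook equivalent of Henderson's equations with plug-in variances.
    """
    p, q, m = X.shape[1], Z.shape[1], M.shape[1]
    C = np.hstack([X, Z, M])
    pen = np.concatenate([np.zeros(p), np.full(q, s_e / s_a), np.full(m, s_e / s_g)])
    sol = linalg.solve(C.T @ C + np.diag(pen), C.T @ y, assume_a="sym")
    return sol[:p], sol[p:p + q], sol[p + q:]


def _sim_mixed(rng, n, q, m, s_a, s_g, s_e):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    Z = rng.normal(size=(n, q))
    M = rng.normal(size=(n, m))
    beta = rng.normal(size=3)
    u = rng.normal(0, np.sqrt(s_a), size=q)
    v = rng.normal(0, np.sqrt(s_g), size=m)
    y = X @ beta + Z @ u + M @ v + rng.normal(0, np.sqrt(s_e), size=n)
    return y, X, Z, M


# ------------------------------------------------------------ single REML

def test_reml_null_variance_reduces_to_ols(rng):
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([2.0, 1.5]) + rng.normal(0, 1.0, size=n)
    Z = rng.normal(size=(n, 40))  # no random signal in y
    s_u, s_e, fit = reml_single_component(y, X, Z_random=Z)
    assert s_u == pytest.approx(0.0, abs=1e-6)
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(fit.fixed_effects.to_numpy(), beta_ols, atol=1e-6)


def test_reml_recovers_variances_in_simulation():
    """Median estimates over seeds land near the generative components."""
    est_u, est_e = [], []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        n, q = 200, 300
        X = np.ones((n, 1))
        Z = rng.normal(size=(n, q))
        true_u, true_e = 0.002, 0.6
        y = (Z @ rng.normal(0, np.sqrt(true_u), size=q)
             + rng.normal(0, np.sqrt(true_e), size=n))
        s_u, s_e, _ = reml_single_component(y, X, Z_random=Z)
        est_u.append(s_u)
        est_e.append(s_e)
    assert np.median(est_u) == pytest.approx(0.002, rel=0.2)
    assert np.median(est_e) == pytest.approx(0.6, rel=0.2)


def test_reml_rejects_nonfinite_response(rng):
    X = np.ones((10, 1))
    y = np.r_[np.nan, np.zeros(9)]
    with pytest.raises(ValueError, match="non-finite"):
        reml_single_component(y, X, Z_random=rng.normal(size=(10, 3)))


def test_reml_reduces_aliased_fixed_effects(rng):
    n = 60
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])  # third column aliased
    Z = rng.normal(size=(n, 20))
    y = X[:, 1] + Z @ rng.normal(0, 0.2, size=20) + rng.normal(size=n)
    _, _, fit = reml_single_component(y, X, Z_random=Z)
    assert len(fit.fixed_effects) == 2


def test_reml_optimum_is_local_maximum(rng):
    """The restricted likelihood at the optimum beats bracketing ratios."""
    from megs.mixed_models import _neg_restricted_ll, _reml_profile

    n, q = 150, 100
    X = np.ones((n, 1))
    Z = rng.normal(size=(n, q))
    y = Z @ rng.normal(0, 0.1, size=q) + rng.normal(size=n)
    s_u, s_e, fit = reml_single_component(y, X, Z_random=Z)
    lam_opt = fit.meta["log10_ratio"]
    xi, eta, df = _reml_profile(y, X, Z @ Z.T)
    f_opt = _neg_restricted_ll(lam_opt, xi, eta**2, df)
    for delta in (-0.5, 0.5):
        assert f_opt <= _neg_restricted_ll(lam_opt + delta, xi, eta**2, df) + 1e-9


# ------------------------------------------------------- two-component fit

@pytest.mark.parametrize("shape", [(50, 100, 30), (60, 20, 10)])
def test_two_component_matches_ridge_oracle(rng, shape):
    n, q, m = shape
    s_a, s_g, s_e = 0.01, 0.05, 0.8
    y, X, Z, M = _sim_mixed(rng, n, q, m, s_a, s_g, s_e)
    beta_o, u_o, v_o = _ridge_oracle(y, X, Z, M, s_a, s_g, s_e)
    for solver in ("kernel", "columns"):
        fit = fit_two_component(y, X, Z, M, s_a, s_g, s_e, solver=solver)
        np.testing.assert_allclose(fit.fixed_effects.to_numpy(), beta_o, atol=1e-8)
        np.testing.assert_allclose(fit.random_effects["snp"].to_numpy(), u_o, atol=1e-8)
        np.testing.assert_allclose(fit.random_effects["asv"].to_numpy(), v_o, atol=1e-8)


def test_two_component_collapses_to_single_as_asv_variance_vanishes(rng):
    n, q, m = 60, 80, 20
    y, X, Z, M = _sim_mixed(rng, n, q, m, 0.01, 0.0, 0.8)
    s_a, s_e, fit_single = reml_single_component(y, X, Z_random=Z, effect_name="snp")
    base = predict(fit_single, X[:, :len(fit_single.fixed_effects)], snp=Z)
    prev_gap = np.inf
    for frac in (1e-2, 1e-4, 1e-6):
        fit = fit_two_component(y, X, Z, M, s_a, s_a * frac, s_e)
        pred = predict(fit, X, snp=Z, asv=M)
        gap = np.max(np.abs(pred - base))
        assert gap < prev_gap + 1e-12
        prev_gap = gap
    assert prev_gap < 1e-6


def test_two_component_rejects_nonpositive_residual(rng):
    y, X, Z, M = _sim_mixed(rng, 30, 10, 5, 0.1, 0.1, 0.5)
    with pytest.raises(ValueError, match="residual"):
        fit_two_component(y, X, Z, M, 0.1, 0.1, 0.0)


def test_marker_permutation_equivariance(rng):
    n, q, m = 40, 30, 10
    y, X, Z, M = _sim_mixed(rng, n, q, m, 0.05, 0.02, 0.5)
    fit = fit_two_component(y, X, Z, M, 0.05, 0.02, 0.5)
    perm = rng.permutation(q)
    fit_p = fit_two_component(y, X, Z[:, perm], M, 0.05, 0.02, 0.5)
    np.testing.assert_allclose(fit_p.random_effects["snp"].to_numpy(),
                               fit.random_effects["snp"].to_numpy()[perm], atol=1e-9)
    np.testing.assert_allclose(predict(fit_p, X, snp=Z[:, perm], asv=M),
                               predict(fit, X, snp=Z, asv=M), atol=1e-9)


def test_prediction_shift_equivariance(rng):
    y, X, Z, M = _sim_mixed(rng, 40, 30, 10, 0.05, 0.02, 0.5)
    fit0 = fit_two_component(y, X, Z, M, 0.05, 0.02, 0.5)
    fit1 = fit_two_component(y + 7.0, X, Z, M, 0.05, 0.02, 0.5)
    np.testing.assert_allclose(predict(fit1, X, snp=Z, asv=M),
                               predict(fit0, X, snp=Z, asv=M) + 7.0, atol=1e-8)


def test_predict_validates_column_identity(rng):
    y, X, Z, M = _sim_mixed(rng, 30, 10, 5, 0.1, 0.1, 0.5)
    fit = fit_two_component(y, X, Z, M, 0.1, 0.1, 0.5)
    with pytest.raises(ValueError, match="columns"):
        predict(fit, X, snp=Z[:, :5], asv=M)
    with pytest.raises(ValueError, match="component"):
        predict(fit, X, genotype=Z)


# ------------------------------------------------------------------ G-BLUP

def _one_obs_design(n):
    df = pd.DataFrame({
        "genotype": [f"G{i}" for i in range(n)],
        "treatment": ["HN"] * n,
        "block": ["B1"] * n,
        "splitplot": ["SP1"] * n,
        "splitplot_block": ["SPB1"] * n,
    })
    df.index = pd.Index([f"p{i}" for i in range(n)], name="plot_id")
    return df


def test_gblup_identity_grm_is_scalar_shrinkage(rng):
    n = 120
    design = _one_obs_design(n)
    g_true = rng.normal(0, 1.0, size=n)
    y = 5.0 + g_true + rng.normal(0, 1.0, size=n)
    grm = Grm(individual_ids=list(design["genotype"]), matrix=np.eye(n))
    fit = fit_gblup_genotype(y, design, grm)
    s_g, s_e = fit.variance_components["sigma2_g"], fit.variance_components["sigma2_e"]
    shrink = s_g / (s_g + s_e)
    resid = y - fit.fixed_effects["intercept"]
    np.testing.assert_allclose(fit.random_effects["genotype"].to_numpy(),
                               shrink * resid, atol=1e-6)


def test_gblup_exchangeable_clones_get_equal_blups(rng):
    n = 30
    design = _one_obs_design(n)
    A = np.eye(n)
    A[0, 1] = A[1, 0] = 1.0  # G0 and G1 are genetic clones
    A[0, 0] = A[1, 1] = 1.0
    y = rng.normal(size=n)
    y[1] = y[0]  # identical records for the clone pair
    grm = Grm(individual_ids=list(design["genotype"]), matrix=A)
    fit = fit_gblup_genotype(y, design, grm)
    blups = fit.random_effects["genotype"]
    assert blups["G0"] == pytest.approx(blups["G1"], abs=1e-9)


def test_gblup_missing_genotype_rejected(rng):
    design = _one_obs_design(5)
    grm = Grm(individual_ids=[f"G{i}" for i in range(4)], matrix=np.eye(4))
    with pytest.raises(ValueError, match="G4"):
        fit_gblup_genotype(rng.normal(size=5), design, grm)


def test_gblup_with_groups_adds_component(small_ds):
    from megs import additive_relationship
    from megs.microbiome import aggregate_taxa

    design = small_ds.design[small_ds.design["treatment"] == "LN"]
    y = small_ds.phenotype.loc[design.index]
    grm = additive_relationship(small_ds.genotypes)
    groups = aggregate_taxa(small_ds.microbiome, "group").values.loc[design.index]
    fit = fit_gblup_genotype(y, design, grm, asv_groups=groups)
    assert set(fit.random_effects) == {"genotype", "group"}
    assert fit.variance_components["sigma2_group"] >= 0
    assert len(fit.random_effects["group"]) == groups.shape[1]


# ------------------------------------------------------------ ASV variance

def test_estimate_asv_variance_null_and_signal(rng, small_ds):
    from megs.evaluation import PredictionData

    data = PredictionData.from_simulated(small_ds)
    # null response: independent noise cannot be attributed to ASVs
    y_null = rng.normal(size=len(data.y))
    s_null, _, _ = estimate_asv_variance(y_null, data.design, data.pcs, data.M)
    assert s_null * data.M.shape[1] < 0.15
    s_sig, _, _ = estimate_asv_variance(data.y, data.design, data.pcs, data.M)
    assert s_sig > 0


def test_fixed_coder_unseen_level_warns(balanced_design):
    coder = FixedCoder(factors=("treatment", "block"))
    coder.fit(balanced_design)
    new = balanced_design.iloc[:2].copy()
    new.loc[new.index[0], "block"] = "B9"
    with pytest.warns(UserWarning, match="B9"):
        X = coder.transform(new)
    assert X.shape[1] == len(coder.columns_)
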