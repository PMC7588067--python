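"""Random-intercept REML solver against independent oracles."""

import numpy as np
import pytest

from phenosig.lmm import conditional_residuals, fit_random_intercept
from phenosig.model import compute_pcs, fit_lmem_residuals
from phenosig.datasets import combine_experiments
from phenosig.simulate import SimulationConfig, simulate_dataset


def balanced_oneway_reml_oracle(Y, n_per_group):
    """Closed-form REML for the balanced one-way random-intercept model:
    sigma2 = MSW, sigma2_u = max(0, (MSB - MSW) / n), BLUP_e =
    shrinkage * (group mean - grand mean) with shrinkage
    sigma2_u / (sigma2_u + sigma2 / n)."""
    G = Y.shape[0]
    E = Y.shape[1] // n_per_group
    n = n_per_group
    grouped = Y.reshape(G, E, n)
    group_means = grouped.mean(axis=2)
    grand = Y.mean(axis=1)
    msb = n * ((group_means - grand[:, None]) ** 2).sum(axis=1) / (E - 1)
    msw = ((grouped - group_means[:, :, None]) ** 2).sum(axis=(1, 2)) / (E * (n - 1))
    s2u = np.maximum(0.0, (msb - msw) / n)
    shrink = s2u / (s2u + msw / n)
    blups = shrink[:, None] * (group_means - grand[:, None])
    return msw, s2u, blups


@pytest.fixture(scope="module")
def balanced_problem():
    rng = np.random.default_rng(12)
    E, n, G = 5, 8, 100
    groups = np.repeat([f"e{i}" for i in range(E)], n)
    Y = (
        rng.normal(0, 0.7, size=(G, E)).repeat(n, axis=1)
        + rng.normal(0, 1, size=(G, E * n))
        + rng.normal(7, 1, size=(G, 1))
    )
    return Y, groups, n


def test_balanced_reml_matches_anova_closed_form(balanced_problem):
    Y, groups, n = balanced_problem
    fit = fit_random_intercept(Y, np.ones((Y.shape[1], 1)), groups)
    s2, s2u, blups = balanced_oneway_reml_oracle(Y, n)
    interior = s2u > 0
    np.testing.assert_allclose(fit.sigma2[interior], s2[interior], atol=1e-6)
    np.testing.assert_allclose(fit.sigma2_u[interior], s2u[interior], atol=1e-6)
    np.testing.assert_allclose(fit.blups[interior], blups[interior], atol=1e-6)
    # the boundary is the OLS fallback, and BLUPs vanish there
    np.testing.assert_array_equal(fit.ols_fallback, ~interior)
    assert np.abs(fit.blups[~interior]).max() == 0.0
    # in a balanced design the BLUPs sum to ~0 across experiments
    assert np.abs(fit.blups.sum(axis=1)).max() < 1e-8


def test_reml_with_covariates_matches_statsmodels(balanced_problem):
    """Independent reference fit: where the reference optimizer converges the
    estimates agree; everywhere our solution's REML log-likelihood is at
    least as high as the reference's."""
    sm_mlm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
    import warnings as _warnings

    Y, groups, _ = balanced_problem
    rng = np.random.default_rng(5)
    X = np.hstack([np.ones((Y.shape[1], 1)), rng.normal(size=(Y.shape[1], 2))])
    Yx = Y + (rng.normal(size=(Y.shape[0], 2)) @ X[:, 1:].T)
    fit = fit_random_intercept(Yx, X, groups)
    compared = 0
    for g in range(10):
        md = sm_mlm.MixedLM(Yx[g], X, groups)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            ref = md.fit(reml=True)
        theta = fit.sigma2_u[g] / fit.sigma2[g]
        mine = sm_mlm.MixedLMParams.from_components(
            fe_params=fit.beta[g], cov_re=np.array([[theta]])
        )
        theirs = sm_mlm.MixedLMParams.from_components(
            fe_params=ref.fe_params,
            cov_re=np.asarray(ref.cov_re) / ref.scale,
        )
        assert md.loglike(mine) >= md.loglike(theirs) - 1e-6
        if not any(issubclass(w.category, Warning) and "onverge" in str(w.message) for w in caught):
            np.testing.assert_allclose(fit.beta[g], ref.fe_params, atol=2e-2)
            assert fit.sigma2[g] == pytest.approx(ref.scale, rel=5e-2)
            compared += 1
    assert compared >= 3


def test_single_experiment_falls_back_to_gene_centering():
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(20, 10))
    groups = np.array(["e1"] * 10)
    fit = fit_random_intercept(Y, np.ones((10, 1)), groups)
    assert fit.ols_fallback.all()
    resid = conditional_residuals(fit, Y, np.ones((10, 1)), groups)
    centered = Y - Y.mean(axis=1, keepdims=True)
    np.testing.assert_allclose(resid * np.sqrt(fit.sigma2)[:, None], centered, atol=1e-10)


def test_no_offset_boundary_genes_reduce_to_global_centering():
    """With no simulated experiment offsets, genes whose variance-ratio
    estimate hits the zero boundary have residuals equal to gene-centered
    data over the residual SD; genes with a spuriously positive estimate
    legitimately subtract a shrunken experiment mean instead."""
    cfg = SimulationConfig(exp_offset_sd=0.0, n_latent_factors=0, factor_design=(),
                           n_signal_genes=0, n_target_sets=0, n_genes=300, seed=4)
    data = combine_experiments(simulate_dataset(cfg)[0])
    pcs = compute_pcs(data, 2)
    fit, rm = fit_lmem_residuals(data, pcs, 0)
    boundary = fit.ols_fallback
    assert boundary.mean() > 0.3
    Y = data.expr.to_numpy()
    centered = (Y - Y.mean(axis=1, keepdims=True)) / np.sqrt(fit.sigma2)[:, None]
    np.testing.assert_allclose(rm.values.to_numpy()[boundary], centered[boundary], atol=1e-6)


def test_residuals_orthogonal_to_included_pcs(default_data):
    pcs = compute_pcs(default_data, 4)
    _, rm = fit_lmem_residuals(default_data, pcs, 3)
    resid = rm.values.to_numpy()
    resid = resid - resid.mean(axis=1, keepdims=True)
    for k in range(3):
        s = pcs.scores.to_numpy()[:, k]
        s = (s - s.mean()) / s.std()
        corr = (resid / resid.std(axis=1, keepdims=True)) @ s / s.size
        assert np.abs(corr).max() < 0.05


def test_residual_variance_never_increases_with_more_pcs():
    """Fixed-effect projection property, checked in the OLS regime (single
    experiment, where the fit is exactly least squares)."""
    cfg = SimulationConfig(n_experiments=1, n_genes=200, n_signal_genes=0,
                           n_target_sets=0, seed=9)
    data = combine_experiments(simulate_dataset(cfg)[0])
    pcs = compute_pcs(data, 5)
    prev = None
    for p in range(6):
        fit, _ = fit_lmem_residuals(data, pcs, p)
        rss = fit.sigma2 * (data.n_samples - (p + 1))
        if prev is not None:
            assert np.all(rss <= prev + 1e-8)
        prev = rss


def test_pc_scores_centered_orthogonal_and_variance_ordered(default_data):
    pcs = compute_pcs(default_data, 5)
    scores = pcs.scores.to_numpy()
    assert np.abs(scores.mean(axis=0)).max() < 1e-8
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6
    assert np.all(np.diff(pcs.variance_fractions) <= 1e-12)
    # p_max = 0 is the no-PC model
    empty = compute_pcs(default_data, 0)
    assert empty.scores.shape[1] == 0
    assert empty.design(0).shape == (default_data.n_samples, 1)


def test_pc1_clusters_by_experiment_when_offsets_dominate():
    cfg = SimulationConfig(exp_offset_sd=3.0, noise_sd=1.0, n_latent_factors=0,
                           factor_design=(), n_signal_genes=0, n_target_sets=0,
                           n_genes=400, seed=10)
    data = combine_experiments(simulate_dataset(cfg)[0])
    pcs = compute_pcs(data, 4)
    assert pcs.variance_fractions[0] > pcs.variance_fractions[1:].max()
    from scipy import stats as sps

    scores = pcs.scores.to_numpy()[:, 0]
    exp_ids = data.meta["experiment_id"].to_numpy()
    groups = [scores[exp_ids == e] for e in np.unique(exp_ids)]
    assert sps.f_oneway(*groups).pvalue < 1e-10
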