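"""Generator contracts: reproducibility, null calibration, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosig.datasets import ValidationError, combine_experiments
from phenosig.simulate import (
    SimulationConfig,
    default_config,
    simulate_dataset,
    simulate_query_experiment,
)


def _class_diff(expr, meta):
    mut = meta["class"].to_numpy() == "mutant"
    return expr.to_numpy()[:, mut].mean(axis=1) - expr.to_numpy()[:, ~mut].mean(axis=1)


def test_same_seed_bit_identical():
    cfg = default_config(seed=7, n_genes=200, n_gene_sets=10)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    for (ea, ma), (eb, mb) in zip(a[0], b[0]):
        pd.testing.assert_frame_equal(ea, eb)
        pd.testing.assert_frame_equal(ma, mb)
    assert a[1].sets == b[1].sets
    assert a[2].signal_gene_ids == b[2].signal_gene_ids
    pd.testing.assert_series_equal(a[2].effects, b[2].effects)


def test_null_t_test_type_i_error():
    """With no planted signal each gene's two-sample t-test is exactly
    calibrated; the across-gene rejection fraction sits at the nominal 5%.
    Latent factors are disabled here because shared factor scores correlate
    genes and inflate the variance of the fraction without biasing it."""
    cfg = SimulationConfig(
        n_experiments=1, n_genes=5000, n_signal_genes=0, n_target_sets=0,
        n_latent_factors=0, factor_design=(), seed=2,
    )
    (expr, meta), = simulate_dataset(cfg)[0]
    mut = meta["class"].to_numpy() == "mutant"
    res = stats.ttest_ind(expr.to_numpy()[:, mut], expr.to_numpy()[:, ~mut], axis=1)
    frac = float((res.pvalue < 0.05).mean())
    assert abs(frac - 0.05) < 0.01


def test_signal_effects_recovered_within_ci():
    """The observed mutant-control difference per signal gene is an unbiased
    estimate of the planted signed delta."""
    cfg = default_config(seed=3)
    experiments, _, truth = simulate_dataset(cfg)
    diffs = np.mean([_class_diff(expr.loc[truth.signal_gene_ids], meta) for expr, meta in experiments], axis=0)
    err = diffs - truth.effects.to_numpy()
    se = err.std(ddof=1) / np.sqrt(err.size)
    assert abs(err.mean()) < 1.96 * se + 1e-12


def test_experiment_offsets_drive_leading_pcs(null_data):
    """Between-experiment offsets put experiment identity, not class, on the
    leading PCs of the combined null data."""
    from phenosig.model import compute_pcs

    pcs = compute_pcs(null_data, 3)
    scores = pcs.scores.to_numpy()
    exp_ids = null_data.meta["experiment_id"].to_numpy()
    classes = null_data.classes
    groups = [scores[exp_ids == e, 0] for e in np.unique(exp_ids)]
    p_exp = stats.f_oneway(*groups).pvalue
    p_cls = stats.f_oneway(scores[classes == "mutant", 0], scores[classes == "control", 0]).pvalue
    assert p_exp < 1e-6
    assert p_cls > 0.01


@pytest.mark.parametrize(
    "kwargs",
    [
        {"set_size_range": (10, 5000)},
        {"n_signal_genes": 5000},
        {"n_latent_factors": 3},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValidationError):
        SimulationConfig(n_genes=2000, **kwargs)


def test_query_without_phenotype_has_uniform_pvalues():
    """No gene is class-associated in a phenotype-free query. Latent factors
    are disabled: they correlate genes, which inflates the variance of the
    KS statistic without biasing any per-gene test."""
    cfg = default_config(seed=4, n_latent_factors=0, factor_design=())
    _, _, truth = simulate_dataset(cfg)
    expr, meta = simulate_query_experiment(cfg, truth, carries_phenotype=False, seed=11)
    mut = meta["class"].to_numpy() == "mutant"
    res = stats.ttest_ind(expr.to_numpy()[:, mut], expr.to_numpy()[:, ~mut], axis=1)
    assert stats.kstest(res.pvalue, "uniform").pvalue > 0.01


def test_query_noise_free_limit_recovers_exact_effects():
    cfg = SimulationConfig(noise_sd=0.0, exp_offset_sd=0.0, n_latent_factors=0,
                           factor_design=(), seed=5)
    _, _, truth = simulate_dataset(cfg)
    expr, meta = simulate_query_experiment(cfg, truth, carries_phenotype=True, seed=6)
    diff = pd.Series(_class_diff(expr, meta), index=expr.index)
    assert np.allclose(diff[truth.signal_gene_ids], truth.effects, atol=1e-12)
    assert np.allclose(diff.drop(truth.signal_gene_ids), 0.0, atol=1e-12)


def test_query_same_seed_identical_and_universe_checked():
    cfg = default_config(seed=8, n_genes=300)
    _, _, truth = simulate_dataset(cfg)
    q1 = simulate_query_experiment(cfg, truth, carries_phenotype=True, seed=9)
    q2 = simulate_query_experiment(cfg, truth, carries_phenotype=True, seed=9)
    pd.testing.assert_frame_equal(q1[0], q2[0])
    other = default_config(seed=8, n_genes=301)
    with pytest.raises(ValidationError):
        simulate_query_experiment(other, truth, carries_phenotype=True)


def test_designated_target_sets_contain_signal_fraction(default_sim):
    _, gene_sets, truth = default_sim
    signal = set(truth.signal_gene_ids)
    for name in truth.target_set_names:
        members = gene_sets[name]
        frac = len(members & signal) / len(members)
        assert frac == pytest.approx(0.5, abs=0.1)
    decoy_fracs = [
        len(gene_sets[name] & signal) / len(gene_sets[name])
        for name in gene_sets.names()
        if name.startswith("decoy")
    ]
    assert np.mean(decoy_fracs) < 0.2
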