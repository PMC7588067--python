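"""Rank-based set enrichment, BH-FDR, and PC-count selection."""

from itertools import combinations

import numpy as np
import pytest

from phenosig.datasets import GeneSetCollection, ValidationError, combine_experiments
from phenosig.enrichment import (
    bh_fdr,
    enrich_ranking,
    enrichment_table,
    select_pc_count,
    wilcoxon_set_test,
)
from phenosig.simulate import clean_config, confounded_config, simulate_dataset


def exact_ranksum_p(G, member_ranks):
    """Exhaustive one-sided null: probability that a uniformly placed set has
    rank-sum <= the observed one."""
    m = len(member_ranks)
    observed = sum(member_ranks)
    hits = total = 0
    for placement in combinations(range(1, G + 1), m):
        total += 1
        if sum(placement) <= observed:
            hits += 1
    return hits / total


def test_top_ranks_exact_small_case():
    ranking = [f"g{i}" for i in range(1, 11)]
    stat, p = wilcoxon_set_test(ranking, {"g1", "g2", "g3"})
    assert stat == 6.0
    assert p == pytest.approx(1 / 120, abs=1e-12)


def test_exact_mode_matches_enumeration_for_small_problems():
    rng = np.random.default_rng(0)
    for G in (6, 9, 12):
        ranking = [f"g{i}" for i in range(G)]
        for m in range(1, 6):
            for _ in range(6):
                ranks = sorted(rng.choice(G, size=m, replace=False) + 1)
                members = {ranking[r - 1] for r in ranks}
                _, p = wilcoxon_set_test(ranking, members)
                assert p == pytest.approx(exact_ranksum_p(G, ranks), abs=1e-10)


def test_bottom_ranked_set_is_anti_enriched():
    ranking = [f"g{i}" for i in range(50)]
    _, p = wilcoxon_set_test(ranking, set(ranking[-5:]))
    assert p > 0.99


def test_normal_approximation_close_to_exact():
    """Continuity-corrected normal p within 0.02 of the exact null at
    |set| = 8, G = 20."""
    from scipy import stats as sps

    rng = np.random.default_rng(1)
    G, m = 20, 8
    ranking = [f"g{i}" for i in range(G)]
    for _ in range(40):
        ranks = sorted(rng.choice(G, size=m, replace=False) + 1)
        members = [ranking[r - 1] for r in ranks]
        other = [g for g in ranking if g not in members]
        exact = sps.mannwhitneyu(np.array(ranks, float),
                                 np.array([ranking.index(g) + 1 for g in other], float),
                                 alternative="less", method="exact").pvalue
        approx = sps.mannwhitneyu(np.array(ranks, float),
                                  np.array([ranking.index(g) + 1 for g in other], float),
                                  alternative="less", method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02


def test_random_sets_give_uniform_pvalues():
    rng = np.random.default_rng(2)
    G = 500
    ranking = [f"g{i}" for i in range(G)]
    pvals = []
    for _ in range(500):
        members = set(rng.choice(ranking, size=25, replace=False))
        pvals.append(wilcoxon_set_test(ranking, members)[1])
    from scipy import stats as sps

    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_degenerate_sets_rejected():
    ranking = ["g1", "g2", "g3"]
    with pytest.raises(ValidationError):
        wilcoxon_set_test(ranking, set())
    with pytest.raises(ValidationError):
        wilcoxon_set_test(ranking, {"g1", "g2", "g3"})


def bh_stepup_oracle(pvals):
    """Direct evaluation of q_i = min_{j>=i} m p_(j) / j mapped to input order."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.2,), (0.2,)),
        ((0.3, 0.3, 0.3), (0.3, 0.3, 0.3)),
    ],
)
def test_bh_fdr_known_values(pvals, expected):
    np.testing.assert_allclose(bh_fdr(pvals), expected, atol=1e-12)


def test_bh_fdr_matches_stepup_oracle_and_order_invariant():
    rng = np.random.default_rng(3)
    p = rng.random(200) ** 2
    q = bh_fdr(p)
    np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
    assert np.all(q >= p - 1e-15)
    perm = rng.permutation(p.size)
    np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.2])


def test_enrich_ranking_targets_vs_decoys(default_sim, default_fit):
    _, gene_sets, truth = default_sim
    results = enrich_ranking(default_fit.ranking, gene_sets)
    table = enrichment_table(results).set_index("set_name")
    assert (table.loc[truth.target_set_names, "q_value"] < 0.05).all()
    decoys = table.drop(truth.target_set_names)
    assert (decoys["q_value"] >= 0.05).mean() >= 0.9
    # reversing the ranking destroys one-sided enrichment of the targets
    reversed_results = enrich_ranking(default_fit.ranking[::-1], gene_sets)
    rev = enrichment_table(reversed_results).set_index("set_name")
    assert (rev.loc[truth.target_set_names, "p_value"] > 0.5).all()


def test_enrichment_equivariant_under_gene_relabeling(default_fit, default_sim):
    _, gene_sets, truth = default_sim
    ranking = default_fit.ranking
    mapping = {g: f"x{g}" for g in ranking}
    relabeled_sets = GeneSetCollection(
        sets={n: frozenset(mapping.get(g, g) for g in s) for n, s in gene_sets.items()}
    )
    a = enrichment_table(enrich_ranking(ranking, gene_sets)).set_index("set_name")
    b = enrichment_table(
        enrich_ranking([mapping[g] for g in ranking], relabeled_sets)
    ).set_index("set_name")
    np.testing.assert_allclose(a["p_value"], b.loc[a.index, "p_value"], atol=1e-12)


def test_set_outside_universe_dropped_with_warning():
    ranking = [f"g{i}" for i in range(30)]
    sets = GeneSetCollection(
        sets={"inside": frozenset(ranking[:5]), "outside": frozenset({"zz1", "zz2"})}
    )
    with pytest.warns(UserWarning, match="outside"):
        results = enrich_ranking(ranking, sets)
    assert [r.set_name for r in results] == ["inside"]
    only_out = GeneSetCollection(sets={"outside": frozenset({"zz1"})})
    with pytest.warns(UserWarning):
        with pytest.raises(ValidationError):
            enrich_ranking(ranking, only_out)


def test_pc_selection_confounded_vs_clean():
    """A class-correlated latent factor masks the signal until >= 1 PC is
    absorbed; without latent factors the smallest-p tie-break keeps p = 0."""
    exps, sets, truth = simulate_dataset(confounded_config(seed=2))
    sel = select_pc_count(combine_experiments(exps), sets, truth.target_set_names, p_max=4)
    assert sel.selected_p >= 1
    assert sel.n_significant[sel.selected_p] > sel.n_significant[0]

    exps2, sets2, truth2 = simulate_dataset(clean_config(seed=2))
    sel2 = select_pc_count(combine_experiments(exps2), sets2, truth2.target_set_names, p_max=4)
    assert sel2.selected_p == 0
    assert any("tie-break" in line for line in sel2.trace)


def test_pc_selection_pmax_zero_trivial(default_data, default_sim):
    _, sets, truth = default_sim
    sel = select_pc_count(default_data, sets, truth.target_set_names, p_max=0)
    assert sel.selected_p == 0
    assert list(sel.n_significant) == [0]
    with pytest.raises(ValidationError, match="unknown target"):
        select_pc_count(default_data, sets, ["missing_set"], p_max=0)
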