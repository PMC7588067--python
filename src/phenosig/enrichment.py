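"""Rank-based gene-set enrichment and PC-count selection.

A gene set is tested by comparing the ranks of its members against the ranks
of non-members with the Wilcoxon rank-sum test, one-sided toward "members
rank closer to the top" — the ranking comes from the per-gene logistic
significance irrespective of effect direction, so enrichment is directional
in rank only. BH step-up FDR is applied across the tested collection.

The PC count for the mixed model is selected by refitting the signature at
every p in 0..p_max and counting how many user-designated phenotype-related
("target") sets reach q < 0.05; the smallest p achieving the maximal count
wins. The full per-p table is returned so the automated choice can be
overridden by inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CombinedDataset, GeneSetCollection, ValidationError
from .model import compute_pcs, fit_lmem_residuals, gene_logistic_scan, ranking_from_stats

_EXACT_MAX_SET = 8
_EXACT_MAX_UNIVERSE = 20


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int  # after intersection with the ranked universe
    rank_sum: float
    p_value: float
    q_value: float = np.nan


@dataclass
class PcSelectionResult:
    """Per-PC-count enrichment of the target sets and the selected count."""

    table: pd.DataFrame  # columns: n_pcs, set_name, set_size, rank_sum, p_value, q_value
    selected_p: int
    n_significant: dict[int, int]  # per p: target sets with q < 0.05
    trace: list[str]


def wilcoxon_set_test(ranking: list[str], members) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test that ``members`` rank near the top.

    ``ranking`` is the full gene ranking, best first. Returns the members'
    rank-sum statistic and the one-sided p-value (small when members
    concentrate at the top). Uses the exact null for small problems
    (|set| <= 8 and universe <= 20), otherwise the tie/continuity-corrected
    normal approximation.
    """
    universe = list(ranking)
    G = len(universe)
    member_set = set(members)
    member_ranks = np.array([i + 1 for i, g in enumerate(universe) if g in member_set], dtype=float)
    m = member_ranks.size
    if m == 0 or m == G:
        raise ValidationError("set must be a proper non-empty subset of the ranked universe")
    other_ranks = np.setdiff1d(np.arange(1, G + 1, dtype=float), member_ranks)
    method = "exact" if (m <= _EXACT_MAX_SET and G <= _EXACT_MAX_UNIVERSE) else "asymptotic"
    res = stats.mannwhitneyu(member_ranks, other_ranks, alternative="less", method=method)
    return float(member_ranks.sum()), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_ranking(
    ranking: list[str], gene_sets: GeneSetCollection, min_size: int = 1
) -> list[EnrichmentResult]:
    """Test every gene set against a ranking; FDR across all tested sets.

    Sets entirely outside the ranked universe are dropped with a warning;
    members outside the universe are ignored at use time.
    """
    universe = set(ranking)
    results: list[EnrichmentResult] = []
    for name, members in gene_sets.items():
        inter = members & universe
        if len(inter) < min_size or len(inter) == 0:
            warnings.warn(f"gene set {name!r} does not intersect the ranked universe; dropped",
                          stacklevel=2)
            continue
        if len(inter) == len(universe):
            warnings.warn(f"gene set {name!r} covers the whole universe; dropped", stacklevel=2)
            continue
        rank_sum, p = wilcoxon_set_test(ranking, inter)
        results.append(EnrichmentResult(name, len(inter), rank_sum, p))
    if not results:
        raise ValidationError("no gene set intersects the ranked universe")
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "set_size": r.set_size,
                "rank_sum": r.rank_sum,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )


def select_pc_count(
    data: CombinedDataset,
    gene_sets: GeneSetCollection,
    target_set_names,
    p_max: int = 7,
    alpha: float = 0.05,
) -> PcSelectionResult:
    """Choose the number of nuisance PCs by target-set enrichment.

    For each p in 0..p_max: mixed-model residuals -> logistic scan ->
    enrichment of all sets, FDR across the collection; the score of p is the
    number of target sets with q < ``alpha``. Selected p maximizes the score,
    ties broken by the smallest p.
    """
    target_set_names = list(target_set_names)
    missing = [t for t in target_set_names if t not in gene_sets]
    if missing:
        raise ValidationError(f"unknown target sets: {missing}")
    if p_max < 0:
        raise ValidationError("p_max must be >= 0")
    pcs = compute_pcs(data, p_max)
    labels = data.classes
    rows = []
    n_significant: dict[int, int] = {}
    trace: list[str] = []
    for p in range(0, min(p_max, pcs.p_max) + 1):
        _, residuals = fit_lmem_residuals(data, pcs, p)
        gene_stats = gene_logistic_scan(residuals, labels)
        ranking = ranking_from_stats(gene_stats)
        results = enrich_ranking(ranking, gene_sets)
        by_name = {r.set_name: r for r in results}
        count = 0
        for t in target_set_names:
            r = by_name.get(t)
            if r is None:
                continue
            rows.append(
                {
                    "n_pcs": p,
                    "set_name": t,
                    "set_size": r.set_size,
                    "rank_sum": r.rank_sum,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
            )
            if r.q_value < alpha:
                count += 1
        n_significant[p] = count
        trace.append(f"p={p}: {count}/{len(target_set_names)} target sets with q < {alpha}")
    best = max(n_significant.values())
    selected = min(p for p, c in n_significant.items() if c == best)
    trace.append(f"selected p={selected} (max significant targets = {best}, smallest-p tie-break)")
    return PcSelectionResult(
        table=pd.DataFrame(rows), selected_p=selected, n_significant=n_significant, trace=trace
    )
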