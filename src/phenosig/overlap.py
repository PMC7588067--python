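"""Cross-experiment overlap of top differentially expressed genes.

Tests whether unrelated control/mutant experiments share more top-ranked
differentially expressed genes than chance — the signature of a global
compensatory transcriptional response to gene perturbation. For many random
sets of experiments, each experiment is ranked by a per-gene Welch t-test,
the top-N lists are intersected pairwise, each overlap is scored by an
upper-tail hypergeometric p-value, and the per-set summary is the median
-log10 p over the pairs. The chance-null distribution repeats the procedure
with uniformly drawn N-gene lists in place of the ranked ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CONTROL, MUTANT, ValidationError


@dataclass(frozen=True)
class OverlapSimConfig:
    """Generator for pools of independent control/mutant experiments.

    Each simulated experiment draws its own differentially expressed genes:
    uniformly from the whole universe when ``shared_module_size`` is 0
    (independent perturbations), or from a fixed ``shared_module_size``-gene
    module common to all experiments (a shared global response).
    """

    n_genes: int = 2000
    n_controls: int = 8
    n_mutants: int = 8
    n_signal_genes: int = 100
    effect_size: float = 1.0
    noise_sd: float = 1.0
    shared_module_size: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes exceeds n_genes")
        if self.shared_module_size and self.n_signal_genes > self.shared_module_size:
            raise ValidationError("n_signal_genes exceeds shared_module_size")
        if self.shared_module_size > self.n_genes:
            raise ValidationError("shared_module_size exceeds n_genes")


@dataclass
class OverlapPermResult:
    """Observed and chance-null distributions of the per-set median
    -log10 hypergeometric overlap p-value."""

    observed_medians: np.ndarray  # one per experiment set
    null_medians: np.ndarray
    pairwise_overlap_counts: list[list[int]]  # per set, per pair
    n_top: int
    universe_size: int

    def null_quantile(self, q: float) -> float:
        return float(np.quantile(self.null_medians, q))


def de_rank_genes(expr: pd.DataFrame, labels) -> list[str]:
    """Rank genes by a per-gene two-sample Welch t-test (ascending p, ties by
    gene ID). Genes constant in both classes are excluded with a warning."""
    labels = np.asarray(labels)
    x = expr.to_numpy()
    a = x[:, labels == MUTANT]
    b = x[:, labels == CONTROL]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each class needs >= 2 samples for the Welch t-test")
    constant = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue)
    if constant.any():
        warnings.warn(f"{constant.sum()} constant gene(s) excluded from DE ranking", stacklevel=2)
    genes = expr.index.to_numpy()
    keep = ~constant & np.isfinite(p)
    order = np.lexsort((genes[keep], p[keep]))
    return list(genes[keep][order])


def hypergeom_overlap_p(G: int, N1: int, N2: int, k: int) -> float:
    """Upper-tail P(X >= k) for the overlap of an N1- and an N2-list drawn
    from a universe of G genes."""
    if not (0 <= k <= min(N1, N2) <= max(N1, N2) <= G):
        raise ValidationError(f"inconsistent overlap counts: G={G}, N1={N1}, N2={N2}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, G, N1, N2))


def _median_neglog10_p(top_lists: Sequence[set], G: int, n_top: int) -> tuple[float, list[int]]:
    neglogs, counts = [], []
    for s1, s2 in combinations(top_lists, 2):
        k = len(s1 & s2)
        counts.append(k)
        p = hypergeom_overlap_p(G, len(s1), len(s2), k)
        neglogs.append(-np.log10(p))
    return float(np.median(neglogs)), counts


def _simulate_experiment(rng: np.random.Generator, cfg: OverlapSimConfig, module: np.ndarray | None):
    G = cfg.n_genes
    n = cfg.n_controls + cfg.n_mutants
    labels = np.array([CONTROL] * cfg.n_controls + [MUTANT] * cfg.n_mutants)
    x = rng.normal(0.0, cfg.noise_sd, size=(G, n))
    if cfg.n_signal_genes:
        pool = module if module is not None else np.arange(G)
        sig = rng.choice(pool, size=cfg.n_signal_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_signal_genes)
        x[np.ix_(sig, labels == MUTANT)] += (signs * cfg.effect_size)[:, None]
    genes = [f"g{i:06d}" for i in range(1, G + 1)]
    return pd.DataFrame(x, index=genes, columns=[f"s{j:02d}" for j in range(n)]), labels


def _subsample(expr: pd.DataFrame, labels: np.ndarray, counts: tuple[int, int], rng) -> tuple[pd.DataFrame, np.ndarray]:
    keep = []
    for cls, want in zip((CONTROL, MUTANT), counts):
        idx = np.flatnonzero(labels == cls)
        if idx.size < want:
            raise ValidationError(f"cannot subsample {want} {cls} samples from {idx.size}")
        keep.extend(rng.choice(idx, size=want, replace=False))
    keep = sorted(keep)
    return expr.iloc[:, keep], labels[keep]


def overlap_experiment(
    experiments: Sequence[tuple[pd.DataFrame, np.ndarray]] | None = None,
    config: OverlapSimConfig | None = None,
    n_sets: int = 1000,
    set_size: int = 5,
    n_top: int = 200,
    seed: int = 0,
    match_counts: tuple[int, int] | None = None,
) -> OverlapPermResult:
    """Permutation analysis of pairwise top-N gene overlap.

    Either draw ``set_size`` experiments per set from a fixed ``experiments``
    pool (optionally subsampled to ``match_counts`` controls/mutants), or
    simulate fresh experiments per set from ``config``. The chance-null draws
    random ``n_top``-gene lists per experiment from a separate seed stream.
    """
    if (experiments is None) == (config is None):
        raise ValidationError("provide exactly one of experiments or config")
    rng = np.random.default_rng(seed)
    null_rng = np.random.default_rng((seed + 1_000_003) % (2**31 - 1))
    if experiments is not None:
        pool = list(experiments)
        if len(pool) < set_size:
            raise ValidationError("experiment pool smaller than set_size")
        G = pool[0][0].shape[0]
    else:
        G = config.n_genes
    if n_top > G:
        raise ValidationError("n_top exceeds the gene universe")
    if set_size < 2:
        raise ValidationError("set_size must be >= 2")

    module = None
    if config is not None and config.shared_module_size:
        module = rng.choice(G, size=config.shared_module_size, replace=False)

    observed, null_medians, all_counts = [], [], []
    for _ in range(n_sets):
        top_lists = []
        if experiments is not None:
            chosen = rng.choice(len(pool), size=set_size, replace=False)
            for i in chosen:
                expr, labels = pool[i]
                if match_counts is not None:
                    expr, labels = _subsample(expr, np.asarray(labels), match_counts, rng)
                top_lists.append(set(de_rank_genes(expr, labels)[:n_top]))
        else:
            for _ in range(set_size):
                expr, labels = _simulate_experiment(rng, config, module)
                top_lists.append(set(de_rank_genes(expr, labels)[:n_top]))
        med, counts = _median_neglog10_p(top_lists, G, n_top)
        observed.append(med)
        all_counts.append(counts)

        null_lists = [
            set(null_rng.choice(G, size=n_top, replace=False).tolist()) for _ in range(set_size)
        ]
        null_med, _ = _median_neglog10_p(null_lists, G, n_top)
        null_medians.append(null_med)

    return OverlapPermResult(
        observed_medians=np.asarray(observed),
        null_medians=np.asarray(null_medians),
        pairwise_overlap_counts=all_counts,
        n_top=n_top,
        universe_size=G,
    )
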