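"""Random-forest validation and scoring of the molecular signature.

Leave-one-out cross-validation is at the experiment level: the mixed-model
residuals (and the PCA feeding them) are computed once on the full combined
dataset, then each experiment in turn is held out, the per-gene logistic scan
and top-N signature are rebuilt from the remaining experiments only, a random
forest is trained on their residuals at the signature genes, and the held-out
samples receive mutant-class probabilities. Computing residuals before
holding out leaks nuisance structure (not class labels) across folds; this is
deliberate and matches the procedure the pipeline validates.

A query experiment is scored by appending it to the reference data as a new
random-effect level, recomputing PCA and residuals on the combined data,
building the signature from the reference samples only, and averaging the
forest's mutant-class probabilities per query class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .datasets import CONTROL, MUTANT, CombinedDataset, ValidationError, combine_experiments
from .model import (
    PCScores,
    ResidualMatrix,
    build_signature,
    compute_pcs,
    fit_lmem_residuals,
    gene_logistic_scan,
)


@dataclass(frozen=True)
class RfConfig:
    """Random-forest settings: 1,000 trees and library defaults otherwise."""

    n_trees: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def fold_seed(self, fold_index: int) -> int:
        return int((self.seed + 7919 * (fold_index + 1)) % (2**31 - 1))


@dataclass
class LoocvResult:
    """Pooled experiment-level LOOCV outcome at one (p, N) operating point."""

    fold_probabilities: dict[str, pd.Series]  # held-out experiment -> P(mutant)
    fold_labels: dict[str, pd.Series]
    pooled_auc: float
    control_ttest_p: float  # pooled held-out control probs vs mu = 0.5
    mutant_ttest_p: float
    fold_ttest_p: pd.DataFrame  # per fold x class two-sided p-values
    n_top: int
    n_pcs: int
    incomplete_folds: list[str] = field(default_factory=list)

    @property
    def pooled_probabilities(self) -> pd.Series:
        return pd.concat(list(self.fold_probabilities.values()))

    @property
    def pooled_labels(self) -> pd.Series:
        return pd.concat(list(self.fold_labels.values()))


@dataclass
class RankingResult:
    """Mean class probabilities for one query experiment."""

    experiment_id: str
    mean_control_probability: float | None
    mean_mutant_probability: float | None
    probabilities: pd.Series
    labels: pd.Series
    n_top: int
    n_pcs: int


def auc(scores, labels) -> float:
    """Mann-Whitney concordance: fraction of (mutant, control) pairs where the
    mutant scores higher, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == MUTANT]
    neg = scores[labels == CONTROL]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _ttest_vs_half(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        return float("nan")
    return float(stats.ttest_1samp(values, 0.5).pvalue)


def _mutant_proba(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = forest.predict_proba(X)
    classes = list(forest.classes_)
    if MUTANT in classes:
        return proba[:, classes.index(MUTANT)]
    return 1.0 - proba[:, classes.index(CONTROL)]


def _fit_forest(X: np.ndarray, y: np.ndarray, rf: RfConfig, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(n_estimators=rf.n_trees, random_state=seed)
    forest.fit(X, y)
    return forest


def loocv(
    data: CombinedDataset,
    p: int,
    n_top: int = 200,
    rf: RfConfig | None = None,
    pcs: PCScores | None = None,
) -> LoocvResult:
    """Experiment-level LOOCV at PC count ``p`` and signature size ``n_top``."""
    results = _loocv_grid(data, p, [n_top], rf=rf, pcs=pcs)
    return results[n_top]


def sweep_top_n(
    data: CombinedDataset,
    p: int,
    n_grid=(50, 100, 200, 500, 1000, 2000, 3000),
    rf: RfConfig | None = None,
    pcs: PCScores | None = None,
) -> dict[int, LoocvResult]:
    """LOOCV across signature sizes with shared residuals and fold splits."""
    n_grid = sorted({int(n) for n in n_grid})
    if max(n_grid) > data.n_genes:
        raise ValidationError("n_grid exceeds the gene count")
    return _loocv_grid(data, p, n_grid, rf=rf, pcs=pcs)


def _loocv_grid(data, p, n_grid, rf=None, pcs=None) -> dict[int, LoocvResult]:
    rf = rf or RfConfig()
    experiments = data.experiments
    if len(experiments) < 3:
        raise ValidationError("experiment-level LOOCV needs >= 3 experiments")
    if pcs is None:
        pcs = compute_pcs(data, p)
    # residuals once on the full dataset (see module docstring)
    _, residuals = fit_lmem_residuals(data, pcs, p)
    resid = residuals.values
    meta = data.meta

    fold_probs: dict[int, dict[str, pd.Series]] = {n: {} for n in n_grid}
    fold_labels: dict[str, pd.Series] = {}
    incomplete: list[str] = []
    fold_rows: dict[int, list] = {n: [] for n in n_grid}

    for fold_index, held in enumerate(experiments):
        held_mask = meta["experiment_id"] == held
        train_samples = meta.index[~held_mask]
        test_samples = meta.index[held_mask]
        train_labels = meta.loc[train_samples, "class"].to_numpy()
        train_resid = residuals.values[train_samples]
        train_rm = ResidualMatrix(
            values=train_resid,
            n_pcs=p,
            experiments=[e for e in experiments if e != held],
            excluded_genes=residuals.excluded_genes,
        )
        gene_stats = gene_logistic_scan(train_rm, train_labels)
        seed = rf.fold_seed(fold_index)
        held_classes = set(meta.loc[test_samples, "class"])
        if held_classes != {CONTROL, MUTANT}:
            incomplete.append(held)
        for n in n_grid:
            signature = build_signature(gene_stats, n_top=n, n_pcs=p)
            X_train = resid.loc[signature.genes, train_samples].to_numpy().T
            X_test = resid.loc[signature.genes, test_samples].to_numpy().T
            forest = _fit_forest(X_train, meta.loc[train_samples, "class"].to_numpy(), rf, seed)
            probs = pd.Series(_mutant_proba(forest, X_test), index=test_samples)
            fold_probs[n][held] = probs
            cls = meta.loc[test_samples, "class"]
            fold_rows[n].append(
                {
                    "experiment": held,
                    CONTROL: _ttest_vs_half(probs[cls == CONTROL].to_numpy()),
                    MUTANT: _ttest_vs_half(probs[cls == MUTANT].to_numpy()),
                }
            )
        fold_labels[held] = meta.loc[test_samples, "class"]

    out: dict[int, LoocvResult] = {}
    for n in n_grid:
        pooled_probs = pd.concat(list(fold_probs[n].values()))
        pooled_labels = pd.concat(list(fold_labels.values()))
        out[n] = LoocvResult(
            fold_probabilities=fold_probs[n],
            fold_labels=fold_labels,
            pooled_auc=auc(pooled_probs.to_numpy(), pooled_labels.to_numpy()),
            control_ttest_p=_ttest_vs_half(pooled_probs[pooled_labels == CONTROL].to_numpy()),
            mutant_ttest_p=_ttest_vs_half(pooled_probs[pooled_labels == MUTANT].to_numpy()),
            fold_ttest_p=pd.DataFrame(fold_rows[n]).set_index("experiment"),
            n_top=n,
            n_pcs=p,
            incomplete_folds=incomplete,
        )
    return out


def rank_experiment(
    query: tuple[pd.DataFrame, pd.DataFrame],
    reference: CombinedDataset,
    p: int,
    n_top: int = 200,
    rf: RfConfig | None = None,
) -> RankingResult:
    """Score a query experiment against a reference phenotype dataset.

    The query joins the reference as a new random-effect level; PCA and
    residuals are recomputed on the combined data, but the signature's gene
    scan uses reference samples only.
    """
    rf = rf or RfConfig()
    query_expr, query_meta = query
    query_id = str(query_meta["experiment_id"].iloc[0])
    if query_meta["experiment_id"].nunique() != 1:
        raise ValidationError("query must be a single experiment")
    if query_id in reference.experiments:
        raise ValidationError(f"query experiment ID {query_id!r} clashes with the reference")
    shared = set(query_expr.index) & set(reference.expr.index)
    if len(shared) < n_top:
        raise ValidationError(
            f"query shares only {len(shared)} genes with the reference; need >= n_top={n_top}"
        )
    combined = combine_experiments([(reference.expr, reference.meta), (query_expr, query_meta)])
    pcs = compute_pcs(combined, p)
    _, residuals = fit_lmem_residuals(combined, pcs, p)

    ref_samples = reference.meta.index
    test_samples = query_meta.index
    ref_rm = ResidualMatrix(
        values=residuals.values[list(ref_samples)],
        n_pcs=p,
        experiments=reference.experiments,
        excluded_genes=residuals.excluded_genes,
    )
    gene_stats = gene_logistic_scan(ref_rm, reference.meta["class"].to_numpy())
    signature = build_signature(gene_stats, n_top=n_top, n_pcs=p, experiments=reference.experiments)

    X_train = residuals.values.loc[signature.genes, list(ref_samples)].to_numpy().T
    X_test = residuals.values.loc[signature.genes, list(test_samples)].to_numpy().T
    forest = _fit_forest(X_train, reference.meta["class"].to_numpy(), rf, rf.fold_seed(0))
    probs = pd.Series(_mutant_proba(forest, X_test), index=test_samples)

    cls = query_meta["class"]
    means = {}
    for c in (CONTROL, MUTANT):
        vals = probs[cls == c]
        means[c] = float(vals.mean()) if len(vals) else None
    return RankingResult(
        experiment_id=query_id,
        mean_control_probability=means[CONTROL],
        mean_mutant_probability=means[MUTANT],
        probabilities=probs,
        labels=cls,
        n_top=n_top,
        n_pcs=p,
    )
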