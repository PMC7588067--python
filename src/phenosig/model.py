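"""Molecular-signature engine.

Pipeline per phenotype: PCA of the combined genes x samples matrix; per-gene
random-intercept mixed model with the first p PC score vectors as fixed
effects and the experiment as the random intercept; normalized conditional
residuals; per-gene logistic regression of class on residual; top-N gene
signature ordered by ascending Wald p-value.

``SignatureModel`` / ``SignatureResults`` present this as a fit()-able model;
the underlying operations (:func:`compute_pcs`, :func:`fit_lmem_residuals`,
:func:`gene_logistic_scan`, :func:`build_signature`) are public and are what
cross-validation and PC selection reuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CombinedDataset, MUTANT, ValidationError
from .lmm import LmemFit, conditional_residuals, fit_random_intercept

_MAX_ABS_ETA = 30.0  # logit beyond which fitted probabilities are 0/1 numerically


@dataclass
class PCScores:
    """Sample scores and variance fractions for PCs 1..p_max of the combined
    gene-centered expression matrix. Scores are mean-zero over samples; the
    sign convention makes each PC's largest-magnitude gene loading positive."""

    scores: pd.DataFrame  # samples x PCs, columns "PC1"...
    variance_fractions: np.ndarray

    @property
    def p_max(self) -> int:
        return self.scores.shape[1]

    def design(self, p: int) -> np.ndarray:
        """Fixed-effect design: intercept plus the first ``p`` score vectors."""
        if not 0 <= p <= self.p_max:
            raise ValidationError(f"p must be in [0, {self.p_max}], got {p}")
        ones = np.ones((self.scores.shape[0], 1))
        return np.hstack([ones, self.scores.to_numpy()[:, :p]])


@dataclass
class ResidualMatrix:
    """Genes x samples normalized conditional residuals at a given PC count."""

    values: pd.DataFrame
    n_pcs: int
    experiments: list[str]
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.values.columns.to_numpy()


@dataclass
class Signature:
    """Ordered top-N signature genes with provenance."""

    genes: list[str]
    n_top: int
    n_pcs: int
    experiments: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


def compute_pcs(data: CombinedDataset, p_max: int) -> PCScores:
    """PCA of the combined dataset after per-gene mean centering.

    Returns sample scores for PCs 1..p_max. ``p_max = 0`` is valid and yields
    an empty score set (the no-PC model).
    """
    G, S = data.expr.shape
    if S < 3:
        raise ValidationError("need at least 3 samples for PCA")
    if p_max > min(G, S) - 1:
        raise ValidationError(f"p_max={p_max} exceeds min(G, S) - 1 = {min(G, S) - 1}")
    X = data.expr.to_numpy()
    centered = X - X.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValidationError("constant expression matrix has no principal components")
    # samples x genes SVD; scores = U * s
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    k = min(p_max, np.sum(s > 1e-12 * s[0]))
    scores = U[:, :k] * s[:k]
    # sign convention: largest-|loading| gene positive per PC
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCScores(
        scores=pd.DataFrame(scores, index=data.expr.columns, columns=cols),
        variance_fractions=fractions[:k],
    )


def fit_lmem_residuals(
    data: CombinedDataset, pcs: PCScores, p: int
) -> tuple[LmemFit, ResidualMatrix]:
    """Per-gene random-intercept REML fit with ``p`` PC fixed effects, and the
    resulting normalized conditional residuals (BLUP-subtracted, scaled by the
    per-gene residual SD). Genes with no residual variance are flagged in the
    fit and listed in ``excluded_genes`` (they are never silently dropped)."""
    X = pcs.design(p)
    groups = data.meta["experiment_id"].to_numpy()
    fit = fit_random_intercept(data.expr.to_numpy(), X, groups)
    resid = conditional_residuals(fit, data.expr.to_numpy(), X, groups)
    excluded = [g for g, bad in zip(data.expr.index, fit.excluded) if bad]
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene(s) with zero residual variance excluded from ranking",
            stacklevel=2,
        )
    values = pd.DataFrame(resid, index=data.expr.index, columns=data.expr.columns)
    return fit, ResidualMatrix(
        values=values, n_pcs=p, experiments=data.experiments, excluded_genes=excluded
    )


# ---------------------------------------------------------------------------
# per-gene logistic scan


def _logistic_irls(x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Newton fits of logit P(y=1) = a + b x for every row of ``x`` at once.

    Returns (a, b, se_b, converged, capped) where ``capped`` marks fits that
    ran into (quasi-)separation and were stopped at the step cap.
    """
    G, n = x.shape
    a = np.zeros(G)
    b = np.zeros(G)
    active = np.ones(G, dtype=bool)
    capped = np.zeros(G, dtype=bool)
    yv = y.astype(float)
    for _ in range(max_iter):
        if not active.any():
            break
        xa = x[active]
        eta = a[active, None] + b[active, None] * xa
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_MAX_ABS_ETA, _MAX_ABS_ETA)))
        w = mu * (1.0 - mu)
        r = yv[None, :] - mu
        g0 = r.sum(axis=1)
        g1 = (xa * r).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * xa).sum(axis=1)
        h11 = (w * xa * xa).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(det <= 1e-300, np.nan, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (-h01 * g0 + h00 * g1) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        # damp huge Newton steps (separation drives |eta| to infinity)
        step = np.maximum(np.abs(da), np.abs(db))
        damp = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        a[active] += damp * da
        b[active] += damp * db
        moved = np.maximum(np.abs(da), np.abs(db)) * damp
        eta_big = np.max(np.abs(a[active, None] + b[active, None] * xa), axis=1) > _MAX_ABS_ETA
        done = moved < tol
        capped_now = eta_big & ~done
        idx = np.flatnonzero(active)
        capped[idx[capped_now]] = True
        active[idx[done | capped_now]] = False
    converged = ~active & ~capped
    # Wald SE from the observed information at the final estimate
    eta = a[:, None] + b[:, None] * x
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_MAX_ABS_ETA, _MAX_ABS_ETA)))
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=1)
    h01 = (w * x).sum(axis=1)
    h11 = (w * x * x).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b = np.sqrt(np.where(det > 0, h00 / det, np.inf))
    separated = capped | ~converged
    return a, b, se_b, converged, separated


def gene_logistic_scan(residuals: ResidualMatrix, labels: np.ndarray | pd.Series) -> pd.DataFrame:
    """Univariate logistic regression (class ~ residual) per gene.

    Returns a DataFrame indexed by gene with columns ``beta``, ``se``,
    ``p_value``, ``separation``, ``excluded`` and ``rank`` (1 = most
    significant). Ranking: ascending p, ties by descending \\|beta\\| then
    lexicographic gene ID. Excluded genes (zero residual variance) receive
    rank NaN.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != residuals.values.shape[1]:
        raise ValidationError("labels must align with residual columns")
    y = (labels == MUTANT).astype(int)
    if y.min() == y.max():
        raise ValidationError("both classes must be present for the logistic scan")

    x = residuals.values.to_numpy()
    gene_ids = residuals.values.index
    excluded = gene_ids.isin(residuals.excluded_genes) | ~np.isfinite(x).all(axis=1)
    constant = np.ptp(x, axis=1) == 0

    beta = np.zeros(len(gene_ids))
    se = np.full(len(gene_ids), np.inf)
    pval = np.ones(len(gene_ids))
    separation = np.zeros(len(gene_ids), dtype=bool)

    fit_mask = ~excluded & ~constant
    if fit_mask.any():
        a, b, se_b, conv, sep = _logistic_irls(x[fit_mask], y)
        z = np.where(np.isfinite(se_b) & (se_b > 0), b / se_b, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        beta[fit_mask] = b
        se[fit_mask] = se_b
        pval[fit_mask] = p
        separation[fit_mask] = sep

    stats_df = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p_value": pval,
            "separation": separation,
            "excluded": excluded,
        },
        index=gene_ids.copy(),
    )
    stats_df.index.name = "gene_id"
    ranked = stats_df.loc[~stats_df["excluded"]]
    order = np.lexsort(
        (ranked.index.to_numpy(), -np.abs(ranked["beta"].to_numpy()), ranked["p_value"].to_numpy())
    )
    ranks = pd.Series(np.empty(len(ranked)), index=ranked.index[order])
    ranks.iloc[:] = np.arange(1, len(ranked) + 1)
    stats_df["rank"] = ranks.reindex(stats_df.index)
    return stats_df


def ranking_from_stats(stats_df: pd.DataFrame) -> list[str]:
    """Ranked gene IDs (best first), excluded genes omitted."""
    kept = stats_df.loc[stats_df["rank"].notna()]
    return list(kept.sort_values("rank").index)


def build_signature(
    stats_df: pd.DataFrame,
    n_top: int = 200,
    n_pcs: int | None = None,
    experiments: list[str] | None = None,
) -> Signature:
    """Top-N genes by the logistic-scan ranking (default N = 200)."""
    if n_top <= 0:
        raise ValidationError("n_top must be positive")
    ranked = ranking_from_stats(stats_df)
    if n_top > len(ranked):
        raise ValidationError(f"n_top={n_top} exceeds {len(ranked)} rankable genes")
    return Signature(
        genes=ranked[:n_top],
        n_top=n_top,
        n_pcs=-1 if n_pcs is None else n_pcs,
        experiments=experiments or [],
    )


# ---------------------------------------------------------------------------
# model / results


class SignatureModel:
    """Molecular-signature model for one phenotype.

    Parameters
    ----------
    data : CombinedDataset
        Combined log2 expression + metadata for the phenotype's experiments.
    n_pcs : int
        Number of consecutive PCs entered as fixed effects.
    p_max : int, optional
        How many PCs to precompute (default max(n_pcs, 7), clipped to the
        rank limit); lets one model instance be refit at several PC counts.
    """

    def __init__(self, data: CombinedDataset, n_pcs: int = 0, p_max: int | None = None):
        self.data = data
        self.n_pcs = int(n_pcs)
        limit = min(data.n_genes, data.n_samples) - 1
        self.p_max = min(max(self.n_pcs, 7) if p_max is None else p_max, limit)
        if self.n_pcs > self.p_max:
            raise ValidationError(f"n_pcs={n_pcs} exceeds p_max={self.p_max}")
        self.pc_scores = compute_pcs(data, self.p_max)

    @classmethod
    def from_experiments(cls, experiments, n_pcs: int = 0, **kwargs) -> "SignatureModel":
        from .datasets import combine_experiments

        return cls(combine_experiments(experiments), n_pcs=n_pcs, **kwargs)

    def fit(self, n_top: int = 200, n_pcs: int | None = None) -> "SignatureResults":
        p = self.n_pcs if n_pcs is None else int(n_pcs)
        lmem, residuals = fit_lmem_residuals(self.data, self.pc_scores, p)
        gene_stats = gene_logistic_scan(residuals, self.data.classes)
        signature = build_signature(
            gene_stats, n_top=n_top, n_pcs=p, experiments=self.data.experiments
        )
        return SignatureResults(self, p, lmem, residuals, gene_stats, signature)


class SignatureResults:
    """Fitted signature: per-gene mixed-model components, normalized
    residuals, logistic-scan statistics, and the ordered top-N signature."""

    def __init__(self, model, n_pcs, lmem, residuals, gene_stats, signature):
        self.model = model
        self.n_pcs = n_pcs
        self.lmem = lmem
        self.residuals = residuals
        self.gene_stats = gene_stats
        self.signature = signature

    @property
    def ranking(self) -> list[str]:
        return ranking_from_stats(self.gene_stats)

    def enrich(self, gene_sets, **kwargs):
        from .enrichment import enrich_ranking

        return enrich_ranking(self.ranking, gene_sets, **kwargs)

    def loocv(self, rf_config=None, n_top: int | None = None):
        from .prediction import loocv

        return loocv(
            self.model.data,
            p=self.n_pcs,
            n_top=self.signature.n_top if n_top is None else n_top,
            rf=rf_config,
            pcs=self.model.pc_scores,
        )

    def summary(self, n_show: int = 10) -> str:
        fit = self.lmem
        med_su = float(np.nanmedian(fit.sigma2_u))
        med_s = float(np.nanmedian(fit.sigma2))
        lines = [
            "Molecular signature (random-intercept LMEM + logistic scan)",
            "=" * 62,
            f"experiments: {', '.join(self.model.data.experiments)}",
            f"samples: {self.model.data.n_samples}   genes: {self.model.data.n_genes}",
            f"PCs as fixed effects: {self.n_pcs}   "
            f"top-N: {self.signature.n_top}",
            f"median sigma2_u: {med_su:.4f}   median sigma2: {med_s:.4f}   "
            f"OLS-fallback genes: {int(fit.ols_fallback.sum())}   "
            f"excluded genes: {int(fit.excluded.sum())}",
            "-" * 62,
            f"{'rank':>4}  {'gene':<10} {'beta':>9} {'p_value':>12}  sep",
        ]
        top = self.gene_stats.sort_values("rank").head(n_show)
        for gene, row in top.iterrows():
            lines.append(
                f"{int(row['rank']):>4}  {gene:<10} {row['beta']:>9.3f} "
                f"{row['p_value']:>12.3e}  {'*' if row['separation'] else ''}"
            )
        return "\n".join(lines)
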