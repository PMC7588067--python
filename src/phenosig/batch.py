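"""Within-experiment batch-effect detection and removal.

Detection: PCA of the gene-centered expression of one experiment; each of the
first k PCs is tested for association with the candidate batch factor by
one-way ANOVA of its sample scores on the factor levels. A batch effect is
flagged when any tested PC is both strongly associated (p < 0.01) and large
(variance fraction >= 0.2); both thresholds are configurable since they are
operating conventions, not estimated quantities.

Correction: gene-wise location adjustment — subtract each factor level's mean
and add back the gene's grand mean — optionally followed by scale
equalization of the within-level SDs to the pooled SD. This is the shared
core of location/scale batch-adjustment methods for single-platform
microarray data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ValidationError


@dataclass
class BatchReport:
    """Per-PC association of sample scores with a candidate batch factor."""

    factor_name: str
    variance_fractions: np.ndarray  # non-increasing, in [0, 1]
    p_values: np.ndarray
    flagged_pcs: list[int]  # 1-based PC indices

    @property
    def batch_effect_detected(self) -> bool:
        return bool(self.flagged_pcs)


def _factor_levels(meta: pd.DataFrame, factor_name: str) -> pd.Series:
    if factor_name not in meta.columns:
        raise ValidationError(f"metadata lacks factor column {factor_name!r}")
    factor = meta[factor_name].astype(str)
    counts = factor.value_counts()
    if len(counts) < 2:
        raise ValidationError(f"factor {factor_name!r} has a single level")
    if (counts < 2).any():
        raise ValidationError(f"every level of {factor_name!r} needs >= 2 samples")
    return factor


def detect_batch_effect(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    factor_name: str,
    n_pcs: int = 3,
    p_threshold: float = 0.01,
    variance_threshold: float = 0.2,
) -> BatchReport:
    """Test the leading PCs of one experiment for association with a factor."""
    factor = _factor_levels(meta.loc[list(expr.columns)], factor_name)
    if "class" in meta.columns:
        partition_like_class = factor.groupby(meta.loc[factor.index, "class"]).nunique().eq(1).all()
        if partition_like_class:
            warnings.warn(
                f"factor {factor_name!r} coincides with the control/mutant classes; "
                "correcting on it would erase the phenotype signal",
                stacklevel=2,
            )
    X = expr.to_numpy()
    centered = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    k = min(n_pcs, np.sum(s > 1e-12 * max(s[0], 1e-300)))
    pvals = np.empty(k)
    flagged = []
    for j in range(k):
        scores = U[:, j] * s[j]
        groups = [scores[factor.to_numpy() == lev] for lev in factor.unique()]
        pvals[j] = stats.f_oneway(*groups).pvalue
        if pvals[j] < p_threshold and fractions[j] >= variance_threshold:
            flagged.append(j + 1)
    return BatchReport(
        factor_name=factor_name,
        variance_fractions=fractions[:k],
        p_values=pvals,
        flagged_pcs=flagged,
    )


def correct_batch(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    factor_name: str,
    mode: str = "location",
) -> pd.DataFrame:
    """Remove gene-wise level offsets of a batch factor.

    ``location``: per gene, map each level's mean to the gene's grand mean
    (grand means preserved exactly). ``location_scale`` additionally rescales
    each level's deviations so the within-level SD equals the pooled
    within-level SD.
    """
    if mode not in ("location", "location_scale"):
        raise ValidationError(f"mode must be location or location_scale, got {mode!r}")
    factor = _factor_levels(meta.loc[list(expr.columns)], factor_name)
    X = expr.to_numpy().astype(float)
    grand = X.mean(axis=1, keepdims=True)
    out = np.empty_like(X)
    level_arrays = {lev: factor.to_numpy() == lev for lev in factor.unique()}

    if mode == "location_scale":
        # pooled within-level SD per gene
        ss, dof = np.zeros(X.shape[0]), 0
        for lev, mask in level_arrays.items():
            sub = X[:, mask]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += mask.sum() - 1
        pooled_sd = np.sqrt(ss / dof)

    for lev, mask in level_arrays.items():
        sub = X[:, mask]
        level_mean = sub.mean(axis=1, keepdims=True)
        adjusted = sub - level_mean + grand
        if mode == "location_scale":
            level_sd = sub.std(axis=1, ddof=1, keepdims=True)
            if np.any(level_sd == 0):
                level_sd = np.where(level_sd == 0, 1.0, level_sd)
            adjusted = (sub - level_mean) * (pooled_sd[:, None] / level_sd) + grand
        out[:, mask] = adjusted
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
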