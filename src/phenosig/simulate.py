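"""Synthetic multi-experiment control/mutant expression data.

The generator emulates the statistical structure the signature pipeline
assumes in real repository data: per-gene baselines, per-gene-per-experiment
offsets (lab/platform/normalization shifts), sample-level latent factors
(sex/tissue analogues, optionally correlated with the control/mutant class or
recorded as batch factors), a planted set of phenotype-signal genes with
random-sign log2 effects, and i.i.d. Gaussian noise:

    x[g,s] = mu[g] + a[g,e(s)] + sum_k lambda[g,k] f[k,s]
             + delta[g] * 1[s mutant] * 1[g in signal] + eps[g,s]

A matching gene-set collection is produced in which designated "target" sets
are preferentially populated with signal genes and the remaining decoy sets
are uniform draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import (
    CONTROL,
    MUTANT,
    GeneSetCollection,
    ValidationError,
    write_expression_matrix,
    write_gmt,
    write_json,
    write_metadata,
)


@dataclass(frozen=True)
class FactorSpec:
    """One latent factor.

    level
        ``"experiment"``: one standard-normal score per experiment, shared by
        all its samples. ``"sample"``: an independent score per sample.
    distribution
        ``"normal"`` scores, or ``"binary"`` (+/-0.5, balanced within each
        experiment and class — a tissue-like batch factor).
    class_correlation
        For sample-level normal factors: correlation with the centered
        class indicator, f = rho * c + sqrt(1 - rho^2) * z with c = +/-1.
    loading_sd
        Per-factor override of the gene-loading SD (log2 units).
    record
        Whether the factor appears as a categorical metadata column
        (binary factors only).
    """

    name: str
    level: str = "sample"
    distribution: str = "normal"
    class_correlation: float = 0.0
    loading_sd: float | None = None
    record: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("sample", "experiment"):
            raise ValidationError(f"factor level must be sample/experiment, got {self.level!r}")
        if self.distribution not in ("normal", "binary"):
            raise ValidationError(f"factor distribution must be normal/binary, got {self.distribution!r}")
        if not -1.0 <= self.class_correlation <= 1.0:
            raise ValidationError("class_correlation must be in [-1, 1]")
        if self.class_correlation and self.level != "sample":
            raise ValidationError("class_correlation requires a sample-level factor")
        if self.record and self.distribution != "binary":
            raise ValidationError("only binary factors can be recorded in metadata")


def _default_factors() -> tuple[FactorSpec, ...]:
    return (
        FactorSpec("latent_exp", level="experiment"),
        FactorSpec("latent_sample", level="sample"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator (all in log2 units)."""

    n_experiments: int = 5
    n_controls_per_exp: int | Sequence[int] = 8
    n_mutants_per_exp: int | Sequence[int] = 8
    n_genes: int = 2000
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    exp_offset_sd: float = 0.5
    n_latent_factors: int = 2
    loading_sd: float = 0.5
    factor_design: tuple[FactorSpec, ...] = field(default_factory=_default_factors)
    n_signal_genes: int = 100
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.25
    noise_sd: float = 1.0
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 50)
    n_target_sets: int = 3
    target_set_signal_fraction: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_experiments", "n_genes", "n_gene_sets"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_latent_factors < 0 or self.n_signal_genes < 0:
            raise ValidationError("n_latent_factors and n_signal_genes must be >= 0")
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes exceeds n_genes")
        for name in ("baseline_sd", "exp_offset_sd", "loading_sd", "effect_size_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValidationError("set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValidationError("set_size_range exceeds n_genes")
        if not 0.0 <= self.target_set_signal_fraction <= 1.0:
            raise ValidationError("target_set_signal_fraction must be in [0, 1]")
        if self.n_target_sets > self.n_gene_sets:
            raise ValidationError("n_target_sets exceeds n_gene_sets")
        if self.n_latent_factors != len(self.factor_design):
            raise ValidationError(
                "factor_design length must equal n_latent_factors "
                f"({len(self.factor_design)} != {self.n_latent_factors})"
            )

    def counts(self, which: str) -> list[int]:
        raw = self.n_controls_per_exp if which == CONTROL else self.n_mutants_per_exp
        if np.isscalar(raw):
            counts = [int(raw)] * self.n_experiments
        else:
            counts = [int(c) for c in raw]
            if len(counts) != self.n_experiments:
                raise ValidationError("per-experiment counts must match n_experiments")
        if any(c < 1 for c in counts):
            raise ValidationError("sample counts must be >= 1")
        return counts


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated dataset (for evaluation and queries)."""

    gene_ids: list[str]
    signal_gene_ids: list[str]
    effects: pd.Series  # delta_g over signal genes, signed, log2 units
    factor_scores: pd.DataFrame  # samples x factors
    target_set_names: list[str]
    baselines: pd.Series  # mu_g, reused by query simulation

    def __post_init__(self) -> None:
        unknown = set(self.signal_gene_ids) - set(self.gene_ids)
        if unknown:
            raise ValidationError(f"signal genes outside gene universe: {sorted(unknown)[:5]}")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:06d}" for i in range(1, n + 1)]


def _simulate_one_experiment(
    rng: np.random.Generator,
    config: SimulationConfig,
    exp_id: str,
    n_control: int,
    n_mutant: int,
    baselines: np.ndarray,
    loadings: np.ndarray,
    signal_idx: np.ndarray,
    effects: np.ndarray,
    carries_phenotype: bool = True,
    null_factors: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One experiment's expression, metadata and factor scores."""
    G = config.n_genes
    n = n_control + n_mutant
    sample_ids = [f"{exp_id}_s{j:02d}" for j in range(1, n + 1)]
    classes = np.array([CONTROL] * n_control + [MUTANT] * n_mutant)
    mutant = (classes == MUTANT).astype(float)

    meta = pd.DataFrame({"experiment_id": exp_id, "class": classes}, index=sample_ids)
    meta.index.name = "sample_id"

    x = np.tile(baselines[:, None], (1, n))
    x += rng.normal(0.0, config.exp_offset_sd, size=(G, 1))  # a_{g,e}

    scores = np.zeros((n, len(config.factor_design)))
    for k, spec in enumerate(config.factor_design):
        if spec.distribution == "binary":
            f = np.zeros(n)
            levels = np.empty(n, dtype=object)
            for cls in (CONTROL, MUTANT):
                idx = np.flatnonzero(classes == cls)
                half = np.resize([-0.5, 0.5], idx.size)
                f[idx] = half
                levels[idx] = np.where(half < 0, "A", "B")
            if spec.record:
                meta[spec.name] = levels
        elif spec.level == "experiment":
            f = np.full(n, rng.normal())
        else:
            z = rng.normal(size=n)
            rho = spec.class_correlation if not null_factors else 0.0
            c = 2.0 * mutant - 1.0
            f = rho * c + np.sqrt(max(0.0, 1.0 - rho**2)) * z
        scores[:, k] = f
        x += np.outer(loadings[:, k], f)

    if carries_phenotype and signal_idx.size:
        x[signal_idx] += np.outer(effects, mutant)
    x += rng.normal(0.0, config.noise_sd, size=(G, n))

    expr = pd.DataFrame(x, index=_gene_ids(G), columns=sample_ids)
    factor_cols = [spec.name for spec in config.factor_design]
    scores_df = pd.DataFrame(scores, index=sample_ids, columns=factor_cols)
    return expr, meta, scores_df


def _simulate_gene_sets(
    rng: np.random.Generator, config: SimulationConfig, gene_ids: list[str], signal_idx: np.ndarray
) -> tuple[GeneSetCollection, list[str]]:
    G = config.n_genes
    lo, hi = config.set_size_range
    all_idx = np.arange(G)
    nonsignal_idx = np.setdiff1d(all_idx, signal_idx)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    target_names: list[str] = []
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        is_target = i < config.n_target_sets and signal_idx.size > 0
        if is_target:
            n_sig = min(int(round(size * config.target_set_signal_fraction)), signal_idx.size)
            sig = rng.choice(signal_idx, size=n_sig, replace=False)
            rest = rng.choice(nonsignal_idx, size=size - n_sig, replace=False)
            members = np.concatenate([sig, rest])
            name = f"target_{i + 1:02d}"
            target_names.append(name)
            descriptions[name] = "phenotype-related set (enriched in planted signal genes)"
        else:
            members = rng.choice(all_idx, size=size, replace=False)
            name = f"decoy_{i + 1:03d}"
            descriptions[name] = "decoy set (uniform draw)"
        sets[name] = frozenset(gene_ids[j] for j in members)
    return GeneSetCollection(sets=sets, descriptions=descriptions), target_names


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[tuple[pd.DataFrame, pd.DataFrame]], GeneSetCollection, SimulatedTruth]:
    """Simulate per-experiment expression + metadata, gene sets, and truth.

    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = _gene_ids(G)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    loadings = np.zeros((G, len(config.factor_design)))
    for k, spec in enumerate(config.factor_design):
        sd = config.loading_sd if spec.loading_sd is None else spec.loading_sd
        loadings[:, k] = rng.normal(0.0, sd, size=G)

    signal_idx = np.sort(rng.choice(G, size=config.n_signal_genes, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_signal_genes)
    effects = signs * rng.normal(config.effect_size_mean, config.effect_size_sd, size=config.n_signal_genes)

    n_controls = config.counts(CONTROL)
    n_mutants = config.counts(MUTANT)
    experiments = []
    factor_frames = []
    for e in range(config.n_experiments):
        exp_id = f"e{e + 1:02d}"
        expr, meta, scores = _simulate_one_experiment(
            rng, config, exp_id, n_controls[e], n_mutants[e], baselines, loadings, signal_idx, effects
        )
        experiments.append((expr, meta))
        factor_frames.append(scores)

    gene_sets, target_names = _simulate_gene_sets(rng, config, gene_ids, signal_idx)
    truth = SimulatedTruth(
        gene_ids=gene_ids,
        signal_gene_ids=[gene_ids[j] for j in signal_idx],
        effects=pd.Series(effects, index=[gene_ids[j] for j in signal_idx], name="delta"),
        factor_scores=pd.concat(factor_frames, axis=0),
        target_set_names=target_names,
        baselines=pd.Series(baselines, index=gene_ids, name="mu"),
    )
    return experiments, gene_sets, truth


def simulate_query_experiment(
    config: SimulationConfig,
    truth: SimulatedTruth,
    carries_phenotype: bool,
    seed: int | None = None,
    experiment_id: str = "query",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One fresh experiment on the same gene universe as ``truth``.

    With ``carries_phenotype`` the planted signal genes carry the same signed
    effects as the training data (fresh experiment offset, factors and noise);
    otherwise no gene is associated with the class labels.
    """
    if len(truth.gene_ids) != config.n_genes or truth.gene_ids != _gene_ids(config.n_genes):
        raise ValidationError("truth gene universe incompatible with config")
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    G = config.n_genes
    loadings = np.zeros((G, len(config.factor_design)))
    for k, spec in enumerate(config.factor_design):
        sd = config.loading_sd if spec.loading_sd is None else spec.loading_sd
        loadings[:, k] = rng.normal(0.0, sd, size=G)
    gene_index = pd.Index(truth.gene_ids)
    signal_idx = gene_index.get_indexer(truth.signal_gene_ids)
    expr, meta, _ = _simulate_one_experiment(
        rng,
        config,
        experiment_id,
        config.counts(CONTROL)[0],
        config.counts(MUTANT)[0],
        truth.baselines.to_numpy(),
        loadings,
        np.asarray(signal_idx),
        truth.effects.to_numpy(),
        carries_phenotype=carries_phenotype,
        null_factors=not carries_phenotype,
    )
    return expr, meta


# ---------------------------------------------------------------------------
# convenience configurations


def default_config(seed: int = 1, **overrides) -> SimulationConfig:
    """The reference study conditions: 5 experiments of 8+8 samples, 2,000
    genes, 100 planted signal genes (effect 1.0 +/- 0.25, random sign), noise
    SD 1.0, experiment-offset SD 0.5, two latent factors, 50 gene sets of
    size 20-50 with 3 phenotype-related target sets at 50% signal fraction.
    """
    return SimulationConfig(seed=seed, **overrides)


def null_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Default conditions with no planted signal genes."""
    overrides.setdefault("n_signal_genes", 0)
    overrides.setdefault("n_target_sets", 0)
    return SimulationConfig(seed=seed, **overrides)


def confounded_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Conditions in which a strong sample-level latent factor correlates
    with the control/mutant class within experiments, masking the planted
    signal until the factor is absorbed by PC covariates. The correlation
    (0.45) is strong enough for the factor's loadings (SD 2.0) to swamp the
    per-gene class signal at p = 0, while costing only ~20% of the signal
    variance once the factor's PC is regressed out."""
    overrides.setdefault(
        "factor_design",
        (FactorSpec("confound", level="sample", class_correlation=0.45, loading_sd=2.0),),
    )
    overrides.setdefault("n_latent_factors", 1)
    return SimulationConfig(seed=seed, **overrides)


def clean_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Confound-free conditions (no latent factors at all)."""
    overrides.setdefault("factor_design", ())
    overrides.setdefault("n_latent_factors", 0)
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# on-disk output


def write_dataset(
    experiments: list[tuple[pd.DataFrame, pd.DataFrame]],
    gene_sets: GeneSetCollection,
    truth: SimulatedTruth,
    directory: str | Path,
    seed: int | None = None,
) -> None:
    """Write per-experiment expression TSVs, shared metadata, GMT and truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metas = []
    for expr, meta in experiments:
        exp_id = meta["experiment_id"].iloc[0]
        write_expression_matrix(expr, directory / f"{exp_id}.expr.tsv", seed=seed)
        metas.append(meta)
    write_metadata(pd.concat(metas), directory / "metadata.tsv", seed=seed)
    write_gmt(gene_sets, directory / "gene_sets.gmt")
    write_json(
        {
            "signal_gene_ids": truth.signal_gene_ids,
            "effects": truth.effects.to_dict(),
            "target_set_names": truth.target_set_names,
        },
        directory / "truth.json",
        seed=seed,
    )
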