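"""Data containers and on-disk formats.

Expression matrices are pandas DataFrames with gene IDs as the index and
sample IDs as columns (log2 scale throughout). Sample metadata is a DataFrame
indexed by sample ID with at least ``experiment_id`` and ``class`` columns,
where ``class`` is one of ``control`` / ``mutant``. Gene sets use the GMT
format (one set per line: name, description, tab-separated member IDs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__

CONTROL = "control"
MUTANT = "mutant"
CLASSES = (CONTROL, MUTANT)


class PhenosigError(Exception):
    """Base class for user-facing errors."""


class FormatError(PhenosigError):
    """Malformed input file."""


class ValidationError(PhenosigError):
    """Inputs violate a documented contract."""


# ---------------------------------------------------------------------------
# validation helpers


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique IDs, all-numeric, finite."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs: {dup[:5]}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dup[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite expression value at gene {expr.index[g]!r}, "
            f"sample {expr.columns[s]!r} (missing values are not imputed)"
        )
    return expr


def validate_metadata(meta: pd.DataFrame, require_class: bool = True) -> pd.DataFrame:
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample IDs in metadata")
    if "experiment_id" not in meta.columns:
        raise ValidationError("metadata lacks required column 'experiment_id'")
    if "class" not in meta.columns:
        raise ValidationError("metadata lacks required column 'class'")
    if require_class:
        bad = set(meta["class"].unique()) - set(CLASSES)
        if bad:
            raise ValidationError(
                f"metadata 'class' must be one of {CLASSES}, found {sorted(bad)}"
            )
    return meta


# ---------------------------------------------------------------------------
# containers


@dataclass
class CombinedDataset:
    """Aligned expression matrix and sample metadata for >= 1 experiments.

    ``expr`` is genes x samples; ``meta`` is indexed by sample ID in the same
    column order. ``experiments`` preserves first-appearance order.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression(self.expr)
        validate_metadata(self.meta)
        if list(self.expr.columns) != list(self.meta.index):
            missing = set(self.expr.columns) ^ set(self.meta.index)
            if missing:
                raise ValidationError(
                    f"expression/metadata sample mismatch: {sorted(missing)[:5]}"
                )
            # same samples, different order: align metadata to expression
            self.meta = self.meta.loc[self.expr.columns]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.expr.index.to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.expr.columns.to_numpy()

    @property
    def experiments(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.meta["experiment_id"]:
            seen.setdefault(e, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return self.meta["class"].to_numpy()

    def mutant_indicator(self) -> np.ndarray:
        return (self.classes == MUTANT).astype(int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CombinedDataset":
        return CombinedDataset(self.expr[list(sample_ids)], self.meta.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets; names unique, sets non-empty."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def _header_comment(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# phenosig v{__version__}{tail}\n"


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV/CSV (first column = gene IDs).

    ``#``-prefixed header comments are ignored. Any non-numeric or missing
    cell is an error (no imputation), reported with its coordinates.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate gene IDs: {dup[:5]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].apply(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            row = bad.idxmax() if bad.any() else df.index[0]
            raise FormatError(
                f"{path.name}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    na = df.isna()
    if na.to_numpy().any():
        g = na.any(axis=1).idxmax()
        s = na.loc[g].idxmax()
        raise FormatError(
            f"{path.name}: missing value at gene {g!r}, sample {s!r} "
            "(missing values are not imputed)"
        )
    return validate_expression(df.astype(float))


def write_expression_matrix(expr: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        expr.to_csv(fh, sep=sep, index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path.name}: metadata lacks required column 'sample_id'")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        meta.to_csv(fh, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB members...)."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"gene set {name!r} contains duplicated members; deduplicated",
                    stacklevel=2,
                )
            sets[name] = frozenset(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def write_json(obj, path: str | Path, seed: int | None = None) -> None:
    payload = {"_phenosig_version": __version__}
    if seed is not None:
        payload["_seed"] = seed
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# combination


def combine_experiments(
    experiments: Iterable[tuple[pd.DataFrame, pd.DataFrame]],
) -> CombinedDataset:
    """Combine per-experiment (expression, metadata) pairs into one dataset.

    Genes are reduced to the sorted intersection across experiments; samples
    are concatenated in input order. Duplicate sample IDs across experiments
    and an empty gene intersection are errors.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValidationError("no experiments to combine")
    genes: set | None = None
    for expr, _ in experiments:
        genes = set(expr.index) if genes is None else genes & set(expr.index)
    if not genes:
        raise ValidationError("empty gene intersection across experiments")
    gene_order = sorted(genes)
    exprs, metas = [], []
    seen_samples: set[str] = set()
    for expr, meta in experiments:
        validate_expression(expr)
        validate_metadata(meta)
        clash = seen_samples & set(meta.index)
        if clash:
            raise ValidationError(f"duplicate sample IDs across experiments: {sorted(clash)[:5]}")
        seen_samples |= set(meta.index)
        exprs.append(expr.loc[gene_order, list(meta.index)])
        metas.append(meta)
    combined_expr = pd.concat(exprs, axis=1)
    combined_meta = pd.concat(metas, axis=0)
    return CombinedDataset(combined_expr, combined_meta)


def load_experiment_dir(directory: str | Path) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Load ``<exp>.expr.tsv`` matrices plus a shared ``metadata.tsv``.

    Returns one (expression, metadata) pair per experiment, split by the
    metadata's ``experiment_id`` column.
    """
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    pairs = []
    for exp_id, sub in meta.groupby("experiment_id", sort=False):
        expr = read_expression_matrix(directory / f"{exp_id}.expr.tsv")
        missing = set(sub.index) - set(expr.columns)
        if missing:
            raise ValidationError(
                f"experiment {exp_id!r}: samples in metadata missing from "
                f"expression: {sorted(missing)[:5]}"
            )
        pairs.append((expr[list(sub.index)], sub))
    return pairs
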