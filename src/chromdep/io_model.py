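"""Core data types, file readers/writers, lineage filtering and configuration.

Matrices are carried as pandas DataFrames inside thin dataclass wrappers so
that axis semantics (cell lines vs genes vs samples) stay explicit at module
boundaries while all numerics remain vectorized.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "DependencyMatrix",
    "CellLineAnnotation",
    "ExpressionMatrix",
    "GeneSetCollection",
    "AnalysisConfig",
    "read_dependency_matrix",
    "read_annotations",
    "read_expression_matrix",
    "filter_lineages",
    "read_gmt",
    "write_matrix_csv",
    "read_matrix_csv",
    "child_seed",
    "run_pipeline",
]

# Float formatting for every CSV the package writes: repr-precision so a
# write/read round trip is exact at 12+ significant digits.
CSV_FLOAT_FORMAT = "%.17g"


@dataclass
class DependencyMatrix:
    """Cell lines x genes probability-of-dependency values, each in [0, 1]."""

    data: pd.DataFrame  # index: cell line IDs, columns: gene symbols

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DataError("duplicate cell line IDs in dependency matrix")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate gene IDs in dependency matrix")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def validate(self) -> None:
        arr = self.values
        if np.isnan(arr).any():
            raise DataError("dependency matrix contains missing values")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise DataError("dependency values must lie in [0, 1]")


@dataclass
class CellLineAnnotation:
    """Per-cell-line metadata: lineage label plus optional flags."""

    cell_line_id: str
    lineage: str
    differentiation_class: str | None = None
    mutation_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2(TPM+1) expression values."""

    data: pd.DataFrame  # index: gene symbols, columns: sample IDs

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> None:
        arr = self.data.to_numpy()
        if not np.isfinite(arr).all():
            raise DataError("expression matrix contains non-finite values")
        if arr.size and arr.min() < 0:
            raise DataError("log2(TPM+1) values must be >= 0")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def filter_by_size(self, universe: Sequence[str], min_size: int, max_size: int) -> "GeneSetCollection":
        """Keep sets whose membership *within universe* falls in [min_size, max_size]."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            present = [g for g in members if g in uni]
            if min_size <= len(present) <= max_size:
                kept[name] = members
        return GeneSetCollection(kept, source_tag=self.source_tag)


@dataclass
class AnalysisConfig:
    """Thresholds and run parameters for the full pipeline."""

    min_lines_per_lineage: int = 5
    gene_fdr: float = 0.05
    gene_lfc: float = 0.10
    complex_fdr: float = 0.10
    vip_cutoff: float = 1.0
    vip_cutoff_permissive: float = 0.6
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    n_plsda_iterations: int = 100
    class_ratio_cap: float = 3.0
    rest_mean: str = "of_means"  # {"of_means", "pooled"}
    gate_log_base: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gene_fdr", "gene_lfc", "complex_fdr", "vip_cutoff",
                     "vip_cutoff_permissive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.class_ratio_cap < 1:
            raise ValueError("class_ratio_cap must be >= 1")
        if self.rest_mean not in ("of_means", "pooled"):
            raise ValueError("rest_mean must be 'of_means' or 'pooled'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def child_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from (global seed, stage name).

    Stage order therefore never perturbs another stage's random stream.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)


def _normalize_gene_header(name: str) -> str:
    """Strip the DepMap "SYMBOL (ENTREZID)" suffix; bare symbols pass through."""
    return name.split(" (", 1)[0].strip()


def read_dependency_matrix(path: str | Path,
                           gene_universe: Sequence[str] | None = None) -> DependencyMatrix:
    """Read a cell lines x genes dependency CSV.

    Gene columns are parsed to bare symbols, optionally restricted to
    ``gene_universe``; genes (columns) with any missing value are dropped,
    then any remaining rows with missing values.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas raises many types
        raise FormatError(f"cannot parse dependency CSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"no gene columns in {path}")
    df.columns = [_normalize_gene_header(c) for c in df.columns]
    df.index = df.index.astype(str)
    if df.columns.has_duplicates:
        raise FormatError("duplicate gene symbols after header normalization")
    if gene_universe is not None:
        keep = [g for g in df.columns if g in set(gene_universe)]
        df = df[keep]
    n_genes_before = df.shape[1]
    df = df.dropna(axis=1, how="any")
    dropped_genes = n_genes_before - df.shape[1]
    n_lines_before = df.shape[0]
    df = df.dropna(axis=0, how="any")
    dropped_lines = n_lines_before - df.shape[0]
    if dropped_genes or dropped_lines:
        logger.info("dropped %d genes and %d cell lines with missing values",
                    dropped_genes, dropped_lines)
    if df.empty:
        raise DataError("dependency matrix is empty after NA filtering")
    dep = DependencyMatrix(df.astype(float))
    dep.validate()
    return dep


def read_annotations(path: str | Path) -> list[CellLineAnnotation]:
    """Read cell-line metadata CSV with columns cell_line_id, lineage[, ...]."""
    df = pd.read_csv(path, dtype=str)
    required = {"cell_line_id", "lineage"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation CSV must contain columns {sorted(required)}")
    if df["cell_line_id"].duplicated().any():
        raise FormatError("duplicate cell_line_id in annotation CSV")
    flag_cols = [c for c in df.columns if c.startswith("mut_")]
    out = []
    for _, row in df.iterrows():
        lineage = row["lineage"]
        if not isinstance(lineage, str) or not lineage:
            raise FormatError(f"empty lineage for {row['cell_line_id']}")
        flags = {c[4:]: str(row[c]).lower() in ("1", "true", "yes")
                 for c in flag_cols if pd.notna(row[c])}
        out.append(CellLineAnnotation(
            cell_line_id=row["cell_line_id"],
            lineage=lineage,
            differentiation_class=row.get("differentiation_class") if "differentiation_class" in df.columns and pd.notna(row.get("differentiation_class")) else None,
            mutation_flags=flags,
        ))
    return out


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2(TPM+1) CSV (first column = gene symbol)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"no sample columns in {path}")
    expr = ExpressionMatrix(df.astype(float))
    expr.validate()
    return expr


def filter_lineages(dep: DependencyMatrix,
                    annotations: Sequence[CellLineAnnotation],
                    min_n: int = 5,
                    excluded_lineages: Sequence[str] = ()) -> tuple[DependencyMatrix, list[CellLineAnnotation]]:
    """Drop cell lines whose lineage has fewer than ``min_n`` members.

    Unannotated cell lines (present in the matrix but not the annotation) are
    dropped first; lineages named in ``excluded_lineages`` (e.g. non-cancerous
    lines, supplied explicitly by the caller) are removed before counting.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    ann_map = {a.cell_line_id: a for a in annotations}
    present = [cl for cl in dep.cell_line_ids if cl in ann_map]
    n_unannotated = len(dep.cell_line_ids) - len(present)
    if n_unannotated:
        logger.info("dropping %d unannotated cell lines", n_unannotated)
    excluded = set(excluded_lineages)
    present = [cl for cl in present if ann_map[cl].lineage not in excluded]
    counts: dict[str, int] = {}
    for cl in present:
        counts[ann_map[cl].lineage] = counts.get(ann_map[cl].lineage, 0) + 1
    keep_lineages = {lin for lin, n in counts.items() if n >= min_n}
    if not keep_lineages:
        raise DataError("no lineage satisfies the minimum cell line count")
    kept = [cl for cl in present if ann_map[cl].lineage in keep_lineages]
    logger.info("lineage filter: %d/%d lineages retained (%d cell lines)",
                len(keep_lineages), len(counts), len(kept))
    return (DependencyMatrix(dep.data.loc[kept]),
            [ann_map[cl] for cl in kept])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen = set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("duplicate member %s in set %s deduplicated", g, name)
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    return GeneSetCollection(sets, source_tag=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def write_matrix_csv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a matrix CSV at round-trip-exact float precision."""
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT, index_label=index_label)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def annotations_to_frame(annotations: Sequence[CellLineAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {"cell_line_id": a.cell_line_id, "lineage": a.lineage}
        if a.differentiation_class is not None:
            row["differentiation_class"] = a.differentiation_class
        for k, v in a.mutation_flags.items():
            row[f"mut_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig, inputs: Mapping[str, str | Path],
                 outdir: str | Path) -> dict:
    """Execute all analysis stages in order; see :mod:`chromdep.pipeline`."""
    from . import pipeline  # local import: pipeline imports every stage module

    return pipeline.run_pipeline(config, inputs, outdir)
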