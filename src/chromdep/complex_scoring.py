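"""Aggregate gene-level dependencies into complex-level scores.

A complex score for cell line i is the unweighted mean of the dependency
values of the complex's member genes present in the matrix; members absent
from the matrix are excluded from the mean (logged once per complex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .io_model import DependencyMatrix

logger = logging.getLogger(__name__)

#: Core subunits whose mean dependency defines the Set1C/COMPASS score.
SET1C_CORE_SUBUNITS = ("CXXC1", "SETD1B", "ASH2L", "DPY30", "RBBP5", "WDR5", "WDR82")


@dataclass
class ComplexCatalog:
    """Gene membership per chromatin complex."""

    complexes: dict[str, list[str]]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.complexes.items():
            if len(genes) < 1:
                raise DataError(f"complex {name!r} has no members")
            if len(set(genes)) != len(genes):
                raise DataError(f"complex {name!r} has duplicate members")
        sizes = [len(g) for g in self.complexes.values()]
        if sizes and (min(sizes) < 2 or max(sizes) > 19):
            logger.warning("catalog has complex sizes outside the curated 2-19 range")

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class ComplexScoreMatrix:
    """Cell lines x complexes score matrix plus effective member counts."""

    data: pd.DataFrame  # index: cell line IDs, columns: complex names
    effective_members: dict[str, int]

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def complex_names(self) -> list[str]:
        return list(self.data.columns)


def read_catalog(path: str | Path) -> ComplexCatalog:
    """Read a long-format catalog CSV with columns complex_name, gene_symbol."""
    df = pd.read_csv(path, dtype=str)
    if not {"complex_name", "gene_symbol"}.issubset(df.columns):
        raise FormatError("catalog CSV needs columns complex_name, gene_symbol")
    complexes: dict[str, list[str]] = {}
    for name, grp in df.groupby("complex_name", sort=False):
        complexes[str(name)] = list(dict.fromkeys(grp["gene_symbol"]))
    return ComplexCatalog(complexes)


def write_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    rows = [(name, g) for name, genes in catalog.complexes.items() for g in genes]
    pd.DataFrame(rows, columns=["complex_name", "gene_symbol"]).to_csv(path, index=False)


def complex_scores(dep: DependencyMatrix, catalog: ComplexCatalog) -> ComplexScoreMatrix:
    """Mean dependency over each complex's members present in ``dep``."""
    if len(catalog) == 0:
        raise DataError("empty complex catalog")
    present = set(dep.gene_ids)
    cols = {}
    effective: dict[str, int] = {}
    for name, genes in catalog.complexes.items():
        members = [g for g in genes if g in present]
        if not members:
            logger.info("complex %s has no members in the matrix; omitted", name)
            continue
        if len(members) < len(genes):
            logger.info("complex %s: %d/%d members present", name, len(members), len(genes))
        cols[name] = dep.data[members].mean(axis=1)
        effective[name] = len(members)
    if not cols:
        raise DataError("no catalog gene present in the dependency matrix")
    return ComplexScoreMatrix(pd.DataFrame(cols, index=dep.data.index), effective)


def catalog_summary(catalog: ComplexCatalog) -> dict:
    """Complex count, unique gene count, and size statistics."""
    sizes = np.array([len(g) for g in catalog.complexes.values()], dtype=float)
    if sizes.size == 0:
        return {"n_complexes": 0, "n_unique_genes": 0, "size_min": 0,
                "size_max": 0, "size_median": 0.0, "size_mean": 0.0}
    unique_genes = set()
    for genes in catalog.complexes.values():
        unique_genes.update(genes)
    return {
        "n_complexes": len(catalog),
        "n_unique_genes": len(unique_genes),
        "size_min": int(sizes.min()),
        "size_max": int(sizes.max()),
        "size_median": float(np.median(sizes)),
        "size_mean": float(sizes.mean()),
    }


def set1c_score(dep: DependencyMatrix,
                subunits: Sequence[str] = SET1C_CORE_SUBUNITS) -> pd.Series:
    """Per-cell-line mean dependency over the supplied subunit list."""
    present = [g for g in subunits if g in set(dep.gene_ids)]
    if not present:
        raise DataError("no supplied subunit present in the dependency matrix")
    if len(present) < len(subunits):
        logger.info("set1c score uses %d/%d subunits", len(present), len(subunits))
    return dep.data[present].mean(axis=1).rename("set1c_score")
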