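"""Consensus differential-expression logic across sensitive cell lines.

Consumes per-line statistic tables (log2FC, Wald statistic, p, FDR) produced
by an external count model, flags significance, intersects directions across
sensitive lines against an insensitive reference, and builds the merged
mean-Wald ranking used for pre-ranked enrichment. Also hosts the sample-level
expression PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .enrichment import RankedList
from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene", "log2FC", "stat", "p", "FDR")


@dataclass
class ConsensusSets:
    up: list[str]
    down: list[str]
    audit: pd.DataFrame  # per gene: direction per line and in the reference

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise DataError("consensus up and down sets overlap")


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x PCs
    percent_variance: np.ndarray  # per PC, sums to 100 over all PCs
    cumulative_variance: np.ndarray


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DE_COLUMNS if c not in df.columns and c != "FDR"]
    if missing:
        raise FormatError(f"DE table missing columns: {missing}")
    if "FDR" not in df.columns:
        logger.info("FDR column absent in %s; recomputing from p via BH", path)
        df["FDR"] = bh_adjust(df["p"].to_numpy())
    return df


def pca_expression(expr, n_components: int | None = None) -> PcaResult:
    """Sample-level PCA of per-gene z-scored log2(TPM+1) expression.

    Zero-variance genes are dropped; SVD-based; each component's sign is fixed
    so its largest-|loading| entry is positive.
    """
    data = expr.data  # genes x samples
    if data.shape[1] < 2:
        raise DataError("need at least two samples")
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes before PCA", int((~keep).sum()))
    arr = arr[keep]
    if arr.shape[0] < 2:
        raise DataError("fewer than two non-degenerate genes")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    X = z.T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eigvals = S**2 / (n - 1)
    k = n_components or min(Xc.shape)
    k = min(k, S.size)
    # deterministic sign: largest-|loading| element of each PC positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * S[:k]
    pct = 100.0 * eigvals / eigvals.sum()
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.columns,
                            columns=[f"PC{j+1}" for j in range(k)]),
        percent_variance=pct,
        cumulative_variance=np.cumsum(pct),
    )


def flag_significance(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Direction per gene: up / down / ns at FDR <= cutoff and nonzero log2FC."""
    for col in ("gene", "log2FC", "FDR"):
        if col not in table.columns:
            raise FormatError(f"DE table missing column {col!r}")
    out = table.copy()
    sig = out["FDR"] <= fdr
    out["direction"] = np.where(sig & (out["log2FC"] > 0), "up",
                                np.where(sig & (out["log2FC"] < 0), "down", "ns"))
    return out


def consensus_sets(sensitive_flags: dict[str, pd.DataFrame],
                   reference_flags: pd.DataFrame) -> ConsensusSets:
    """Genes changed in one direction in every sensitive line and not the reference.

    A gene enters consensus_down iff its direction is 'down' in all sensitive
    lines and its reference direction is not 'down' (ns or opposite);
    symmetrically for up. Genes absent from any sensitive table are excluded.
    """
    if len(sensitive_flags) < 2:
        raise DataError("need at least two sensitive lines")
    dirs = {}
    for line, tab in sensitive_flags.items():
        dirs[line] = tab.set_index("gene")["direction"]
    ref_dir = reference_flags.set_index("gene")["direction"]
    common = set.intersection(*(set(d.index) for d in dirs.values()))
    audit_rows = []
    up, down = [], []
    for gene in sorted(common):
        per_line = {line: d.loc[gene] for line, d in dirs.items()}
        ref = ref_dir.loc[gene] if gene in ref_dir.index else "ns"
        verdict = "none"
        if all(v == "up" for v in per_line.values()) and ref != "up":
            up.append(gene)
            verdict = "up"
        elif all(v == "down" for v in per_line.values()) and ref != "down":
            down.append(gene)
            verdict = "down"
        audit_rows.append({"gene": gene, **per_line, "reference": ref,
                           "consensus": verdict})
    return ConsensusSets(up=up, down=down, audit=pd.DataFrame(audit_rows))


def merged_ranking(tables: dict[str, pd.DataFrame]) -> RankedList:
    """Mean Wald statistic over the gene intersection of all tables, ranked."""
    if len(tables) < 2:
        raise DataError("need at least two tables")
    stats_by_line = []
    for line, tab in tables.items():
        if "stat" not in tab.columns:
            raise FormatError(f"table for {line} missing 'stat' column")
        stats_by_line.append(tab.set_index("gene")["stat"].rename(line))
    merged = pd.concat(stats_by_line, axis=1, join="inner")
    if merged.empty:
        raise DataError("empty gene intersection across tables")
    mean_stat = merged.mean(axis=1)
    return RankedList.from_scores(mean_stat, provenance="mean_wald_statistic")
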