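"""One-versus-rest moderated differential dependency analysis.

Per feature (gene or complex score), a no-intercept group-means linear model
is fit across cell lines; each lineage is contrasted against the rest, the
residual variances are shrunk by empirical-Bayes moderation, and moderated
t-statistics with Benjamini-Hochberg FDR (per contrast) yield enrichment
calls. Also hosts row z-scoring, Ward (ward.D2) clustering and the
rank-sum group comparison used for two-group figures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from .errors import DataError
from .io_model import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class OneVsRestFit:
    """Group-means fit: per-feature lineage means, contrasts and variances."""

    features: list[str]
    lineages: list[str]
    group_means: pd.DataFrame       # features x lineages
    logfc: pd.DataFrame             # features x lineages, one-vs-rest contrast
    s2: pd.Series                   # pooled residual variance per feature
    df_residual: int                # n_cell_lines - n_lineages
    v: pd.Series                    # contrast variance multiplier per lineage
    rest_mean: str                  # "of_means" or "pooled"


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for residual variances."""

    d0: float        # prior degrees of freedom, may be math.inf
    s0_sq: float     # prior variance

    def posterior(self, s2: pd.Series, df: float) -> pd.Series:
        """Shrunk variances (d0*s0^2 + df*s2) / (d0 + df)."""
        if math.isinf(self.d0):
            return pd.Series(self.s0_sq, index=s2.index)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0_sq + df * s2) / (self.d0 + df)


def fit_one_vs_rest(matrix: pd.DataFrame, labels: pd.Series,
                    rest_mean: str = "of_means") -> OneVsRestFit:
    """Fit the per-feature group-means model (features x cell lines input).

    ``labels`` maps each column of ``matrix`` to its lineage. The contrast for
    lineage l is its mean minus either the unweighted mean of the other
    lineage means (``of_means``) or the pooled mean over all other cell lines
    (``pooled``).
    """
    labels = pd.Series(labels).astype(str)
    if len(labels) != matrix.shape[1]:
        raise ValueError("labels length must match the number of columns")
    labels.index = matrix.columns
    counts = labels.value_counts()
    if len(counts) < 2:
        raise DataError("need at least two lineages")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DataError(f"singleton lineages not allowed: {bad}")
    if rest_mean not in ("of_means", "pooled"):
        raise ValueError("rest_mean must be 'of_means' or 'pooled'")

    lineages = sorted(counts.index)
    n_l = counts.loc[lineages].to_numpy(dtype=float)
    L = len(lineages)
    n_total = int(n_l.sum())

    X = matrix.to_numpy(dtype=float)
    means = np.empty((X.shape[0], L))
    ss_within = np.zeros(X.shape[0])
    for j, lin in enumerate(lineages):
        cols = (labels == lin).to_numpy()
        block = X[:, cols]
        m = block.mean(axis=1)
        means[:, j] = m
        ss_within += ((block - m[:, None]) ** 2).sum(axis=1)
    df_resid = n_total - L
    s2 = ss_within / df_resid

    logfc = np.empty_like(means)
    v = np.empty(L)
    total_mean = (means * n_l).sum(axis=1) / n_total  # pooled over all lines
    for j in range(L):
        others = [k for k in range(L) if k != j]
        if rest_mean == "of_means":
            rest = means[:, others].mean(axis=1)
            v[j] = 1.0 / n_l[j] + np.sum(1.0 / ((L - 1) ** 2 * n_l[others]))
        else:
            n_rest = n_total - n_l[j]
            rest = (total_mean * n_total - means[:, j] * n_l[j]) / n_rest
            v[j] = 1.0 / n_l[j] + 1.0 / n_rest
        logfc[:, j] = means[:, j] - rest

    features = list(matrix.index)
    return OneVsRestFit(
        features=features,
        lineages=lineages,
        group_means=pd.DataFrame(means, index=features, columns=lineages),
        logfc=pd.DataFrame(logfc, index=features, columns=lineages),
        s2=pd.Series(s2, index=features, name="s2"),
        df_residual=df_resid,
        v=pd.Series(v, index=lineages, name="v"),
        rest_mean=rest_mean,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return x


def moderate_variances(s2: pd.Series, df: float) -> tuple[ModerationParams, pd.Series]:
    """Estimate (d0, s0^2) by matching moments of log residual variances.

    log(s2) for s2 ~ s0^2 * chi2_df/df has mean log(s0^2) + digamma(df/2)
    - log(df/2) and variance trigamma(df/2) under the d0 = inf null; excess
    spread identifies a finite d0 via the trigamma inverse.
    """
    s2 = pd.Series(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise DataError("all residual variances are zero")
    if len(positive) < 10:
        logger.warning("moderation estimated from only %d positive variances", len(positive))
    z = np.log(positive.to_numpy())
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = float(np.clip(d0, 0.0, 1e6))
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    params = ModerationParams(d0=d0, s0_sq=s0_sq)
    return params, params.posterior(s2, df)


def moderated_t(fit: OneVsRestFit, mod: ModerationParams) -> pd.DataFrame:
    """Long-format table of moderated t-statistics and two-sided p-values."""
    post = mod.posterior(fit.s2, fit.df_residual).to_numpy()
    df_total = fit.df_residual + mod.d0
    rows = []
    for lin in fit.lineages:
        lfc = fit.logfc[lin].to_numpy()
        denom = np.sqrt(post * fit.v[lin])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, lfc / np.where(denom > 0, denom, 1.0),
                         np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        rows.append(pd.DataFrame({
            "feature": fit.features, "lineage": lin,
            "logFC": lfc, "t": t, "p": p,
        }))
    return pd.concat(rows, ignore_index=True)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def add_fdr(table: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust p within each lineage contrast (across features)."""
    table = table.copy()
    table["FDR"] = np.nan
    for lin, idx in table.groupby("lineage").groups.items():
        table.loc[idx, "FDR"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    return table


def call_enriched(table: pd.DataFrame, level: str, config: AnalysisConfig) -> pd.DataFrame:
    """Flag lineage-enriched rows by the level-appropriate thresholds."""
    table = table.copy()
    if level == "gene":
        table["enriched"] = (table["FDR"] <= config.gene_fdr) & (table["logFC"] >= config.gene_lfc)
    elif level == "complex":
        table["enriched"] = (table["FDR"] <= config.complex_fdr) & (table["logFC"] > 0)
    else:
        raise ValueError(f"unknown level {level!r}")
    return table


def differential_table(matrix: pd.DataFrame, labels: pd.Series, level: str,
                       config: AnalysisConfig) -> pd.DataFrame:
    """Full gene- or complex-level one-vs-rest differential table."""
    fit = fit_one_vs_rest(matrix, labels, rest_mean=config.rest_mean)
    mod, _ = moderate_variances(fit.s2, fit.df_residual)
    table = add_fdr(moderated_t(fit, mod))
    return call_enriched(table, level, config)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring (sample sd); constant rows are dropped with a warning."""
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant rows before z-scoring", int((~keep).sum()))
    arr = arr[keep]
    sd = sd[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def ward_cluster(matrix: pd.DataFrame, axis: str = "rows") -> tuple[pd.DataFrame, list[str]]:
    """Agglomerative Ward clustering (ward.D2: heights on the distance scale).

    Returns the merge table (left, right, height, size; leaves indexed
    0..n-1, internal nodes n..2n-2) and the dendrogram leaf order as labels.
    """
    if axis == "cols":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    if X.shape[0] < 2:
        raise DataError("need at least two items to cluster")
    Z = hierarchy.linkage(X, method="ward")
    merges = pd.DataFrame({
        "left": Z[:, 0].astype(int),
        "right": Z[:, 1].astype(int),
        "height": Z[:, 2],
        "size": Z[:, 3].astype(int),
    })
    leaf_idx = hierarchy.leaves_list(Z)
    return merges, [str(matrix.index[i]) for i in leaf_idx]


def rank_sum_compare(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 30 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
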