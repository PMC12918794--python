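"""Pre-ranked gene-set enrichment and hypergeometric over-representation.

Ranking can come from per-gene Spearman correlation with a phenotype vector
or any externally supplied score (e.g. mean Wald statistics). The enrichment
score is the classic weighted running-sum statistic; significance uses a
random same-size gene-set null with NES normalization and BH FDR. The
over-representation test is a one-sided hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import DataError
from .io_model import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by descending score (ties broken by gene name)."""

    genes: list[str]
    scores: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise DataError("duplicate genes in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)

    @classmethod
    def from_scores(cls, scores: pd.Series, provenance: str = "") -> "RankedList":
        df = pd.DataFrame({"gene": scores.index.astype(str), "score": scores.to_numpy()})
        df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
        return cls(list(df["gene"]), df["score"].to_numpy(), provenance)

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_phenotype(matrix: pd.DataFrame, phenotype: pd.Series) -> RankedList:
    """Rank genes by Spearman correlation with a per-sample phenotype.

    ``matrix``: genes x samples; ``phenotype`` indexed by sample.
    """
    common = [s for s in matrix.columns if s in phenotype.index]
    if len(common) < 3:
        raise DataError("need at least three shared samples")
    pheno = phenotype.loc[common].to_numpy(dtype=float)
    if not np.isfinite(pheno).all():
        raise DataError("phenotype contains non-finite values")
    if np.all(pheno == pheno[0]):
        raise DataError("constant phenotype")
    sub = matrix[common].to_numpy(dtype=float)
    pheno_rank = stats.rankdata(pheno)
    gene_ranks = stats.rankdata(sub, axis=1)
    pr = pheno_rank - pheno_rank.mean()
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr**2).sum(axis=1) * (pr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (gr @ pr) / np.where(denom > 0, denom, 1.0), 0.0)
    return RankedList.from_scores(pd.Series(rho, index=matrix.index),
                                  provenance="spearman_vs_phenotype")


def enrichment_score(ranked: RankedList, gene_set, weight_exponent: float = 1.0):
    """Weighted running-sum enrichment score, leading edge included.

    Hits step up by |score|^w normalized over hits; misses step down by
    1/(n - |S in ranking|). Returns (ES, running sum, leading-edge genes).
    """
    members = set(gene_set)
    n = len(ranked)
    is_hit = np.array([g in members for g in ranked.genes])
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise DataError("no gene-set member present in the ranking")
    weights = np.abs(ranked.scores) ** weight_exponent
    hit_w = np.where(is_hit, weights, 0.0)
    total_hit_w = hit_w.sum()
    if total_hit_w == 0:  # all member scores zero: fall back to equal steps
        hit_w = is_hit.astype(float)
        total_hit_w = float(n_hits)
    if n_hits == n:
        running = np.cumsum(hit_w / total_hit_w)
        es_idx = int(np.argmax(np.abs(running)))
        es = float(running[es_idx])
    else:
        miss_step = 1.0 / (n - n_hits)
        steps = hit_w / total_hit_w - np.where(is_hit, 0.0, miss_step)
        running = np.cumsum(steps)
        es_idx = int(np.argmax(np.abs(running)))
        es = float(running[es_idx])
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: es_idx + 1], is_hit[: es_idx + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[es_idx:], is_hit[es_idx:]) if h]
    return es, running, leading


def preranked_gsea(ranked: RankedList, collection: GeneSetCollection,
                   min_size: int = 15, max_size: int = 500,
                   n_perm: int = 10_000, seed: int = 0,
                   weight_exponent: float = 1.0) -> pd.DataFrame:
    """Pre-ranked GSEA with a random same-size gene-set null.

    NES = ES / mean(|null ES| of matching sign); one-sided nominal p within
    sign; BH FDR across all tested sets.
    """
    if len(collection) == 0:
        raise DataError("empty gene-set collection")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    present = set(ranked.genes)
    tested: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        in_rank = [g for g in members if g in present]
        if min_size <= len(in_rank) <= max_size:
            tested[name] = in_rank
        else:
            logger.info("set %s excluded by size filter (%d in ranking)", name, len(in_rank))
    if not tested:
        return pd.DataFrame(columns=["set", "size", "ES", "NES", "p", "q", "leading_edge"])

    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight_exponent
    # Shared null per distinct set size: ES of random index subsets.
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({len(v) for v in tested.values()}):
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            null_es[b] = _es_from_indices(idx, weights, n)
        null_by_size[size] = null_es

    rows = []
    for name, members in tested.items():
        es, _, leading = enrichment_score(ranked, members, weight_exponent)
        null_es = null_by_size[len(members)]
        same_sign = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
        if same_sign.size == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            exceed = int((same_sign >= es).sum()) if es >= 0 else int((same_sign <= es).sum())
            p = (exceed + 1) / (same_sign.size + 1)
        rows.append({"set": name, "size": len(members), "ES": es, "NES": nes,
                     "p": p, "leading_edge": "|".join(leading)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["set", "size", "ES", "NES", "p", "q", "leading_edge"]]


def _es_from_indices(hit_idx: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES for a set given as ranking positions (vectorized over hit positions)."""
    size = hit_idx.size
    if size == n:
        return 1.0
    hit_idx = np.sort(hit_idx)
    hit_w = weights[hit_idx]
    total = hit_w.sum()
    if total == 0:
        hit_w = np.ones(size)
        total = float(size)
    miss_step = 1.0 / (n - size)
    # Running sum only changes extremum candidates at hit positions:
    # value just after hit i is cum_hits(i) - miss_step * (pos_i + 1 - (i+1));
    # value just before hit i is cum_hits(i-1) - miss_step * (pos_i - i).
    cum = np.cumsum(hit_w) / total
    after = cum - miss_step * (hit_idx + 1 - np.arange(1, size + 1))
    before = np.concatenate([[0.0], cum[:-1]]) - miss_step * (hit_idx - np.arange(size))
    candidates = np.concatenate([after, before])
    return float(candidates[np.argmax(np.abs(candidates))])


def ora_hypergeometric(query: list[str], collection: GeneSetCollection,
                       universe: list[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment."""
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    dropped = [g for g in query if g not in uni]
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    q = set(query) & uni
    N = len(uni)
    n_q = len(q)
    rows = []
    for name, members in collection.sets.items():
        term = set(members) & uni
        K = len(term)
        if K == 0:
            continue
        k = len(q & term)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_q))
        rows.append({"term": name, "k": k, "K": K, "n": n_q, "N": N,
                     "p": min(p, 1.0), "genes": "|".join(sorted(q & term))})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out[["term", "k", "K", "n", "N", "p", "adj_p", "genes"]]
    return out
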