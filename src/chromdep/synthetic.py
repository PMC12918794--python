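"""Synthetic input generators with recorded ground truth.

Every external input the pipeline consumes can be generated here as a pure
function of its parameters and a seed, with the planted signal (lineage
effects, differentiation classes, mixture components, consensus genes)
serialized alongside the data so downstream stages can be scored without
re-reading generator internals.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complex_scoring import ComplexCatalog, write_catalog
from .differential import bh_adjust
from .errors import DataError
from .io_model import (CellLineAnnotation, DependencyMatrix, ExpressionMatrix,
                       GeneSetCollection, annotations_to_frame, child_seed,
                       write_gmt, write_matrix_csv)
from .state_classification import (MELANOCYTIC_AGGREGATE, STATES,
                                   UNDIFFERENTIATED_AGGREGATE, StateSignature)

logger = logging.getLogger(__name__)


def gen_dependency_matrix(n_lineages: int = 6,
                          lines_per_lineage: int | Sequence[int] = 8,
                          n_genes: int = 200,
                          catalog: ComplexCatalog | None = None,
                          planted: Sequence[tuple[str, str, float]] = (),
                          noise_sd: float = 0.05,
                          seed: int = 0,
                          baseline_beta: tuple[float, float] = (2.0, 8.0)):
    """Dependency matrix with optional planted lineage effects.

    ``planted`` lists (feature, lineage, delta) where feature is either a
    gene name ("G0001"...) or a catalog complex name (effect applied to every
    member). Baseline per gene is Beta(a, b); Gaussian noise is added and the
    result clipped to [0, 1] (clip rate logged; fully clipped effects error).

    Returns (DependencyMatrix, annotations, truth dict).
    """
    rng = np.random.default_rng(seed)
    if isinstance(lines_per_lineage, int):
        sizes = [lines_per_lineage] * n_lineages
    else:
        sizes = list(lines_per_lineage)
        n_lineages = len(sizes)
    lineages = [f"lineage_{i:02d}" for i in range(n_lineages)]
    cell_lines, labels = [], []
    for lin, size in zip(lineages, sizes):
        for j in range(size):
            cell_lines.append(f"{lin}_cl{j:02d}")
            labels.append(lin)
    genes = [f"G{i:04d}" for i in range(n_genes)]

    baseline = rng.beta(*baseline_beta, size=n_genes)
    values = np.tile(baseline, (len(cell_lines), 1))
    label_arr = np.array(labels)

    effects = []
    for feature, lineage, delta in planted:
        if lineage not in lineages:
            raise DataError(f"unknown planted lineage {lineage!r}")
        if catalog is not None and feature in catalog.complexes:
            target_genes = [g for g in catalog.complexes[feature] if g in genes]
        elif feature in genes:
            target_genes = [feature]
        else:
            raise DataError(f"planted feature {feature!r} not a gene or complex")
        rows = label_arr == lineage
        cols = [genes.index(g) for g in target_genes]
        values[np.ix_(rows, cols)] += delta
        effects.append({"feature": feature, "lineage": lineage, "delta": delta,
                        "genes": target_genes})

    values += rng.normal(0.0, noise_sd, size=values.shape)
    below, above = values < 0, values > 1
    n_clipped = int(below.sum() + above.sum())
    if n_clipped:
        logger.info("clipped %d/%d dependency values to [0, 1]",
                    n_clipped, values.size)
    np.clip(values, 0.0, 1.0, out=values)
    for eff in effects:
        rows = label_arr == eff["lineage"]
        cols = [genes.index(g) for g in eff["genes"]]
        if np.all(values[np.ix_(rows, cols)] == 1.0) and eff["delta"] > 0:
            raise DataError(f"planted effect on {eff['feature']} fully clipped")

    dep = DependencyMatrix(pd.DataFrame(values, index=cell_lines, columns=genes))
    ann = [CellLineAnnotation(cl, lin) for cl, lin in zip(cell_lines, labels)]
    truth = {"planted_effects": effects, "lineage_sizes": dict(zip(lineages, sizes)),
             "noise_sd": noise_sd, "seed": seed}
    return dep, ann, truth


def gen_state_signature(genes_per_state: int = 10, seed: int = 0) -> StateSignature:
    """Signature with ``genes_per_state`` synthetic genes per state."""
    assignments = {}
    for state in STATES:
        tag = state.replace(" ", "_").replace("-", "_")
        for i in range(genes_per_state):
            assignments[f"SIG_{tag}_{i:02d}"] = state
    return StateSignature(assignments)


def gen_expression_matrix(n_lines: int, signature: StateSignature,
                          separation_sd: float = 3.0,
                          n_noise_genes: int = 100,
                          melanocytic_fraction: float = 0.6,
                          seed: int = 0,
                          line_names: Sequence[str] | None = None):
    """Expression matrix with two planted differentiation classes.

    Melanocytic-side signature genes shift up by ``separation_sd`` (in noise-sd
    units) in melanocytic-class lines and down otherwise; mirrored for the
    undifferentiated-side states; the excluded intermediate state and
    non-signature genes are pure noise. Values are log2(TPM+1)-like,
    clipped at 0.

    Returns (ExpressionMatrix, class truth Series with 1 = melanocytic-like).
    """
    rng = np.random.default_rng(seed)
    if line_names is not None:
        if len(line_names) != n_lines:
            raise DataError("line_names length must equal n_lines")
        lines = list(line_names)
    else:
        lines = [f"mel_cl{i:02d}" for i in range(n_lines)]
    n_mel = int(round(melanocytic_fraction * n_lines))
    is_mel = np.zeros(n_lines, dtype=bool)
    is_mel[rng.choice(n_lines, size=n_mel, replace=False)] = True

    sig_genes = list(signature.assignments)
    noise_genes = [f"NOISE_{i:04d}" for i in range(n_noise_genes)]
    genes = sig_genes + noise_genes
    base = rng.normal(5.0, 1.0, size=len(genes))
    values = np.tile(base[:, None], (1, n_lines)) + rng.normal(0, 1.0, (len(genes), n_lines))

    half = separation_sd / 2.0
    for gi, g in enumerate(sig_genes):
        state = signature.assignments[g]
        if state in MELANOCYTIC_AGGREGATE:
            values[gi, is_mel] += half
            values[gi, ~is_mel] -= half
        elif state in UNDIFFERENTIATED_AGGREGATE:
            values[gi, is_mel] -= half
            values[gi, ~is_mel] += half
    np.clip(values, 0.0, None, out=values)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=lines))
    truth = pd.Series(is_mel.astype(int), index=lines, name="is_melanocytic")
    return expr, truth


def gen_singlecell_intensities(cell_lines: Sequence[str],
                               markers: Sequence[str],
                               conditions: Sequence[str],
                               n_replicates: int = 3,
                               n_cells: int = 1000,
                               mixture_params: dict | None = None,
                               coupling: dict | None = None,
                               seed: int = 0):
    """Per-cell marker intensities from two-component lognormal mixtures.

    ``mixture_params[(cell_line, condition, marker)]`` supplies
    {high_fraction, mu_low, mu_high, sigma} in log10 units (defaults used
    otherwise). ``coupling[marker] = (driver_marker, prob_same)`` makes a
    marker's latent state copy its driver's with the given probability.
    Replicate cell counts get multiplicative jitter.

    Returns (table DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    defaults = {"high_fraction": 0.8, "mu_low": 1.0, "mu_high": 2.0, "sigma": 0.15}
    mixture_params = mixture_params or {}
    coupling = coupling or {}
    # order markers so drivers are simulated first
    ordered = [m for m in markers if m not in coupling]
    ordered += [m for m in markers if m in coupling]
    rows = []
    truth: dict = {"params": {}, "seed": seed}
    for cl in cell_lines:
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                n = max(1, int(round(n_cells * rng.uniform(0.85, 1.15))))
                states: dict[str, np.ndarray] = {}
                cells = {"cell_line": [cl] * n, "condition": [cond] * n,
                         "replicate": [f"rep{rep}"] * n}
                for m in ordered:
                    p = {**defaults, **mixture_params.get((cl, cond, m), {})}
                    truth["params"][f"{cl}|{cond}|{m}"] = p
                    if m in coupling:
                        driver, prob_same = coupling[m]
                        same = rng.random(n) < prob_same
                        indep = rng.random(n) < p["high_fraction"]
                        state = np.where(same, states[driver], indep)
                    else:
                        state = rng.random(n) < p["high_fraction"]
                    states[m] = state
                    mu = np.where(state, p["mu_high"], p["mu_low"])
                    cells[m] = 10.0 ** rng.normal(mu, p["sigma"])
                rows.append(pd.DataFrame(cells))
    return pd.concat(rows, ignore_index=True), truth


def gen_de_stats_tables(sensitive_lines: Sequence[str] = ("S1", "S2", "S3"),
                        reference_line: str = "REF",
                        n_genes: int = 1000,
                        n_planted_up: int = 40,
                        n_planted_down: int = 40,
                        effect: float = 8.0,
                        seed: int = 0):
    """Per-line DE statistic tables with planted consensus genes.

    Planted genes get a consistent-sign Wald statistic ~N(+-effect, 1) in
    every sensitive line and null behavior in the reference; all other genes
    are exact nulls. Returns (dict line -> table, truth dict).
    """
    if n_planted_up + n_planted_down > n_genes:
        raise DataError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"DE{i:04d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    up_idx = order[:n_planted_up]
    down_idx = order[n_planted_up:n_planted_up + n_planted_down]
    planted_up = sorted(genes[i] for i in up_idx)
    planted_down = sorted(genes[i] for i in down_idx)

    tables = {}
    for line in [*sensitive_lines, reference_line]:
        stat = rng.normal(0.0, 1.0, size=n_genes)
        if line != reference_line:
            stat[up_idx] = rng.normal(effect, 1.0, size=n_planted_up)
            stat[down_idx] = rng.normal(-effect, 1.0, size=n_planted_down)
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(stat))
        tables[line] = pd.DataFrame({
            "gene": genes,
            "log2FC": stat * 0.3,
            "stat": stat,
            "p": p,
            "FDR": bh_adjust(p),
        })
    truth = {"planted_up": planted_up, "planted_down": planted_down,
             "effect": effect, "seed": seed}
    return tables, truth


def default_catalog(n_complexes: int = 10, genes: Sequence[str] | None = None,
                    seed: int = 0) -> ComplexCatalog:
    """Random disjoint-ish catalog over the given gene universe (sizes 2-19)."""
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else [f"G{i:04d}" for i in range(200)]
    complexes = {}
    for i in range(n_complexes):
        size = int(rng.integers(2, 20))
        members = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
        complexes[f"complex_{i:02d}"] = list(members)
    return ComplexCatalog(complexes)


def generate_bundle(outdir: str | Path, seed: int = 0,
                    n_lineages: int = 6, lines_per_lineage: int = 10,
                    n_genes: int = 200, planted_delta: float = 0.3) -> dict:
    """Emit the full synthetic input bundle + truth JSON for the pipeline.

    Plants one enriched complex in one target lineage of the dependency data,
    a two-class expression structure, coupled single-cell mixtures, and
    consensus DE genes. Returns the truth dict (also written to truth.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gene_universe = [f"G{i:04d}" for i in range(n_genes)]
    catalog = default_catalog(n_complexes=10, genes=gene_universe,
                              seed=child_seed(seed, "catalog"))
    target_lineage = "lineage_00"
    target_complex = "complex_00"
    # give the planted complex >= 16 members so its gene set passes the
    # default GSEA minimum-size filter downstream
    rng_cat = np.random.default_rng(child_seed(seed, "target_complex"))
    catalog.complexes[target_complex] = sorted(
        rng_cat.choice(gene_universe, size=16, replace=False))
    dep, ann, dep_truth = gen_dependency_matrix(
        n_lineages=n_lineages, lines_per_lineage=lines_per_lineage,
        n_genes=n_genes, catalog=catalog,
        planted=[(target_complex, target_lineage, planted_delta)],
        noise_sd=0.05, seed=child_seed(seed, "dependency"))
    write_matrix_csv(dep.data, outdir / "dependency.csv", index_label="cell_line_id")
    annotations_to_frame(ann).to_csv(outdir / "annotations.csv", index=False)
    write_catalog(catalog, outdir / "catalog.csv")

    signature = gen_state_signature(genes_per_state=10, seed=child_seed(seed, "signature"))
    pd.DataFrame({"gene": list(signature.assignments),
                  "state": list(signature.assignments.values())}
                 ).to_csv(outdir / "signature.csv", index=False)
    n_expr_lines = min(40, len(dep.cell_line_ids))
    expr, class_truth = gen_expression_matrix(
        n_lines=n_expr_lines, signature=signature, separation_sd=3.0,
        seed=child_seed(seed, "expression"),
        line_names=dep.cell_line_ids[:n_expr_lines])
    write_matrix_csv(expr.data, outdir / "expression.csv", index_label="gene")

    # gene sets: one planted at the top of the set1c-style ranking + nulls
    rng = np.random.default_rng(child_seed(seed, "genesets"))
    sets = {"planted_set": list(catalog.complexes[target_complex])}
    for i in range(8):
        members = sorted(rng.choice(dep.gene_ids, size=20, replace=False))
        sets[f"null_set_{i}"] = list(members)
    write_gmt(GeneSetCollection(sets), outdir / "genesets.gmt")

    sc_params = {}
    for cond, frac in (("si-NTC", 0.85), ("si-TARGET", 0.25)):
        sc_params[("cellA", cond, "markerX")] = {"high_fraction": frac}
        sc_params[("cellA", cond, "markerY")] = {"high_fraction": frac}
    sc_table, sc_truth = gen_singlecell_intensities(
        ["cellA"], ["markerX", "markerY"], ["si-NTC", "si-TARGET"],
        n_replicates=3, n_cells=1500, mixture_params=sc_params,
        coupling={"markerY": ("markerX", 0.95)},
        seed=child_seed(seed, "singlecell"))
    sc_table.to_csv(outdir / "singlecell.csv", index=False)

    de_tables, de_truth = gen_de_stats_tables(seed=child_seed(seed, "de_stats"))
    for line, tab in de_tables.items():
        tab.to_csv(outdir / f"de_{line}.csv", index=False)

    # gene sets over the DE gene universe for the consensus-ranking GSEA
    de_genes = list(de_tables["REF"]["gene"])
    rng_de = np.random.default_rng(child_seed(seed, "de_genesets"))
    de_sets = {"planted_up_set": de_truth["planted_up"],
               "planted_down_set": de_truth["planted_down"]}
    for i in range(6):
        members = sorted(rng_de.choice(de_genes, size=25, replace=False))
        de_sets[f"de_null_set_{i}"] = list(members)
    write_gmt(GeneSetCollection(de_sets), outdir / "de_genesets.gmt")

    truth = {
        "seed": seed,
        "target_lineage": target_lineage,
        "target_complex": target_complex,
        "planted_delta": planted_delta,
        "dependency": dep_truth,
        "classes": class_truth.to_dict(),
        "singlecell": sc_truth,
        "consensus": de_truth,
        "planted_gene_set": "planted_set",
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return truth
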