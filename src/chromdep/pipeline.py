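"""End-to-end pipeline orchestration.

Stages run in a fixed order (complex scoring -> differential dependency ->
clustering -> state classification -> PLS-DA -> enrichment -> gating ->
consensus DE), each writing its CSV outputs under the output directory.
Any stage failure aborts with the stage name. All stochastic stages derive
their seed from (config.rng_seed, stage name), so the run is bit-reproducible
and stage order never perturbs another stage's random stream.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import complex_scoring, consensus_de, differential, enrichment
from . import plsda as plsda_mod
from . import singlecell, state_classification
from .errors import ChromdepError
from .io_model import (AnalysisConfig, annotations_to_frame, child_seed,
                       filter_lineages, read_annotations,
                       read_dependency_matrix, read_expression_matrix,
                       read_gmt, write_matrix_csv)

logger = logging.getLogger(__name__)


class PipelineError(ChromdepError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: AnalysisConfig, inputs: Mapping[str, str | Path],
                 outdir: str | Path) -> dict:
    """Run every stage for which the required inputs are present.

    Required input keys: dependency, annotations, catalog. Optional:
    expression, signature, genesets, de_genesets, singlecell, de_tables
    (mapping line -> path), de_reference (line name), control_condition.
    Returns a dict of stage -> primary output DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log_lines = [f"config: {config.to_dict()}"]

    dep, annotations = _load_core(config, inputs)
    log_lines.append(f"cell_lines={len(dep.cell_line_ids)} genes={len(dep.gene_ids)}")

    scores, catalog = _stage_complex_scores(inputs, dep, outdir)
    results["complex_scores"] = scores.data

    labels = pd.Series({a.cell_line_id: a.lineage for a in annotations})
    gene_table, complex_table = _stage_differential(config, dep, scores, labels, outdir)
    results["gene_differential"] = gene_table
    results["complex_differential"] = complex_table

    _stage_clustering(complex_table, outdir)

    profile = fit = None
    if "expression" in inputs and "signature" in inputs:
        profile, fit = _stage_state_classification(config, inputs, outdir)
        results["state_profile"] = profile

    if profile is not None:
        plsda_out = _stage_plsda(config, dep, profile, outdir)
        if plsda_out is not None:
            results["plsda_vip"] = plsda_out

    if "genesets" in inputs:
        results["gsea_phenotype"] = _stage_enrichment(config, inputs, dep, scores, outdir)

    if "singlecell" in inputs:
        results["fraction_high"] = _stage_gating(config, inputs, outdir)

    if "de_tables" in inputs:
        results["consensus"] = _stage_consensus(config, inputs, outdir)

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


@_stage("load_inputs")
def _load_core(config, inputs):
    dep = read_dependency_matrix(inputs["dependency"])
    annotations = read_annotations(inputs["annotations"])
    dep, annotations = filter_lineages(
        dep, annotations, min_n=config.min_lines_per_lineage,
        excluded_lineages=inputs.get("excluded_lineages", ()))
    return dep, annotations


@_stage("complex_scoring")
def _stage_complex_scores(inputs, dep, outdir):
    catalog = complex_scoring.read_catalog(inputs["catalog"])
    scores = complex_scoring.complex_scores(dep, catalog)
    write_matrix_csv(scores.data, outdir / "complex_scores.csv", "cell_line_id")
    summary = complex_scoring.catalog_summary(catalog)
    pd.DataFrame([summary]).to_csv(outdir / "catalog_summary.csv", index=False)
    return scores, catalog


@_stage("differential_dependency")
def _stage_differential(config, dep, scores, labels, outdir):
    gene_table = differential.differential_table(
        dep.data.T, labels.loc[dep.cell_line_ids], "gene", config)
    gene_table.to_csv(outdir / "gene_differential.csv", index=False)
    complex_table = differential.differential_table(
        scores.data.T, labels.loc[scores.cell_line_ids], "complex", config)
    complex_table.to_csv(outdir / "complex_differential.csv", index=False)
    return gene_table, complex_table


@_stage("clustering")
def _stage_clustering(complex_table, outdir):
    logfc = complex_table.pivot(index="lineage", columns="feature", values="logFC")
    z = differential.zscore_rows(logfc)
    write_matrix_csv(z, outdir / "zscored_complex_logfc.csv", "lineage")
    if z.shape[0] >= 2:
        merges, leaves = differential.ward_cluster(z, axis="rows")
        merges.to_csv(outdir / "row_merge_tree.csv", index=False)
        pd.DataFrame({"leaf": leaves}).to_csv(outdir / "row_leaf_order.csv", index=False)
    if z.shape[1] >= 2:
        merges, leaves = differential.ward_cluster(z, axis="cols")
        merges.to_csv(outdir / "col_merge_tree.csv", index=False)
        pd.DataFrame({"leaf": leaves}).to_csv(outdir / "col_leaf_order.csv", index=False)


@_stage("state_classification")
def _stage_state_classification(config, inputs, outdir):
    expr = read_expression_matrix(inputs["expression"])
    sig = state_classification.read_signature(inputs["signature"])
    profile, fit = state_classification.classify_lines(
        expr, sig, seed=child_seed(config.rng_seed, "state_classification"))
    write_matrix_csv(profile.drop(columns=["assigned_class"]).assign(
        assigned_class=profile["assigned_class"]), outdir / "state_profile.csv",
        "cell_line_id")
    pd.DataFrame([{
        "pi1": fit.weights[0], "pi2": fit.weights[1],
        "mu1": fit.means[0], "mu2": fit.means[1],
        "sd1": fit.sds[0], "sd2": fit.sds[1],
        "boundary": fit.boundary, "log_likelihood": fit.log_likelihood,
        "n_iter": fit.n_iter, "converged": fit.converged,
    }]).to_csv(outdir / "gmm_fit.csv", index=False)
    return profile, fit


@_stage("plsda")
def _stage_plsda(config, dep, profile, outdir):
    common = [cl for cl in dep.cell_line_ids if cl in profile.index]
    if len(common) < 10:
        logger.info("plsda skipped: only %d classified lines with dependency data",
                    len(common))
        return None
    X = dep.data.loc[common]
    y = (profile.loc[common, "assigned_class"]
         == state_classification.MELANOCYTIC_LIKE).astype(int)
    if y.nunique() < 2 or y.value_counts().min() < 5:
        logger.info("plsda skipped: class too small")
        return None
    cfg = AnalysisConfig(**{**config.to_dict(),
                            "rng_seed": child_seed(config.rng_seed, "plsda")})
    agg, cv_table = plsda_mod.run_iterations(X, y, cfg)
    agg.to_csv(outdir / "plsda_vip.csv", index_label="feature")
    cv_table.to_csv(outdir / "plsda_cv.csv", index=False)
    return agg


@_stage("enrichment")
def _stage_enrichment(config, inputs, dep, scores, outdir):
    collection = read_gmt(inputs["genesets"])
    present = set(dep.gene_ids)
    subunits = [g for g in complex_scoring.SET1C_CORE_SUBUNITS if g in present]
    if subunits:
        phenotype = complex_scoring.set1c_score(dep, subunits)
    else:  # synthetic data: use the first complex score as the phenotype
        phenotype = scores.data.iloc[:, 0]
    ranked = enrichment.rank_by_phenotype(dep.data.T, phenotype)
    gsea = enrichment.preranked_gsea(
        ranked, collection, min_size=min(config.gsea_min_size, 15),
        max_size=config.gsea_max_size, n_perm=2000,
        seed=child_seed(config.rng_seed, "enrichment"))
    gsea.to_csv(outdir / "gsea_phenotype.csv", index=False)
    return gsea


@_stage("gating")
def _stage_gating(config, inputs, outdir):
    table = pd.read_csv(inputs["singlecell"])
    control = inputs.get("control_condition", "si-NTC")
    markers = [c for c in table.columns if c not in singlecell.ID_COLUMNS]
    all_fracs, gate_rows, welch_rows = [], [], []
    gates_by_line: dict[str, dict[str, singlecell.GateEntry]] = {}
    for cl in sorted(table["cell_line"].unique()):
        gates_by_line[cl] = {}
        for marker in markers:
            gate = singlecell.pool_and_gate(
                table, marker, cell_line=cl, log_base=config.gate_log_base,
                seed=child_seed(config.rng_seed, f"gate_{cl}_{marker}"))
            gates_by_line[cl][marker] = gate
            gate_rows.append({"cell_line": cl, "marker": marker,
                              "threshold": gate.threshold, "n_cells": gate.n_cells})
            frac = singlecell.fraction_high(table, gate)
            frac.insert(0, "marker", marker)
            frac.insert(0, "cell_line", cl)
            all_fracs.append(frac)
            if control in set(frac["condition"]):
                w = singlecell.welch_replicate_test(frac, "pct_high", control)
                w.insert(0, "marker", marker)
                w.insert(0, "cell_line", cl)
                welch_rows.append(w)
    frac_table = pd.concat(all_fracs, ignore_index=True)
    pd.DataFrame(gate_rows).to_csv(outdir / "gating_thresholds.csv", index=False)
    frac_table.to_csv(outdir / "fraction_high.csv", index=False)
    if welch_rows:
        pd.concat(welch_rows, ignore_index=True).to_csv(outdir / "welch_tests.csv", index=False)
    if len(markers) >= 2:
        quads = []
        for cl, gates in gates_by_line.items():
            q = singlecell.quadrant_fractions(table[table["cell_line"] == cl],
                                              gates[markers[0]], gates[markers[1]])
            q.insert(0, "cell_line", cl)
            quads.append(q)
        pd.concat(quads, ignore_index=True).to_csv(outdir / "quadrants.csv", index=False)
    counts = singlecell.normalized_cell_count(table, control)
    counts.to_csv(outdir / "cell_counts.csv", index=False)
    return frac_table


@_stage("consensus_de")
def _stage_consensus(config, inputs, outdir):
    de_paths = dict(inputs["de_tables"])
    reference = inputs.get("de_reference")
    if reference is None or reference not in de_paths:
        raise ChromdepError("de_reference must name one of de_tables")
    tables = {line: consensus_de.read_de_table(path)
              for line, path in de_paths.items()}
    flags = {line: consensus_de.flag_significance(tab, fdr=config.gene_fdr)
             for line, tab in tables.items()}
    sensitive = {line: f for line, f in flags.items() if line != reference}
    cons = consensus_de.consensus_sets(sensitive, flags[reference])
    pd.DataFrame({"gene": cons.up + cons.down,
                  "direction": ["up"] * len(cons.up) + ["down"] * len(cons.down)}
                 ).to_csv(outdir / "consensus_sets.csv", index=False)
    cons.audit.to_csv(outdir / "consensus_audit.csv", index=False)
    ranked = consensus_de.merged_ranking(
        {line: tab for line, tab in tables.items() if line != reference})
    pd.DataFrame({"gene": ranked.genes, "score": ranked.scores}
                 ).to_csv(outdir / "merged_ranking.csv", index=False)
    if "de_genesets" in inputs:
        collection = read_gmt(inputs["de_genesets"])
        gsea = enrichment.preranked_gsea(
            ranked, collection, min_size=config.gsea_min_size,
            max_size=config.gsea_max_size, n_perm=2000,
            seed=child_seed(config.rng_seed, "consensus_gsea"))
        gsea.to_csv(outdir / "gsea_consensus.csv", index=False)
        universe = ranked.genes
        for direction, genes in (("up", cons.up), ("down", cons.down)):
            if genes:
                ora = enrichment.ora_hypergeometric(genes, collection, universe)
                ora.to_csv(outdir / f"ora_{direction}.csv", index=False)
    return cons
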