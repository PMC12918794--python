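"""Single-cell immunofluorescence gating and condition summaries.

Per-cell marker intensities are log-transformed, pooled across conditions
within a cell line, and gated by the analytic boundary of a two-component
Gaussian mixture (machinery shared with state classification). Downstream
summaries: fraction-high per condition/replicate, 2x2 quadrant fractions,
replicate-level Welch tests, normalized cell counts and delta-% regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .state_classification import GmmFit1D, fit_gmm_1d, gmm_boundary

logger = logging.getLogger(__name__)

#: Required identifier columns in a single-cell table; remaining numeric
#: columns are treated as marker intensities.
ID_COLUMNS = ("cell_line", "condition", "replicate")


@dataclass
class GateEntry:
    cell_line: str
    marker: str
    fit: GmmFit1D
    threshold: float
    log_base: float
    n_cells: int


def _log_transform(values: np.ndarray, log_base: float) -> np.ndarray:
    return np.log(values) / math.log(log_base)


def validate_table(table: pd.DataFrame, markers: list[str]) -> None:
    missing = [c for c in (*ID_COLUMNS, *markers) if c not in table.columns]
    if missing:
        raise DataError(f"single-cell table missing columns: {missing}")


def pool_and_gate(table: pd.DataFrame, marker: str, cell_line: str | None = None,
                  log_base: float = 10.0, seed: int | None = None) -> GateEntry:
    """Fit the pooled log-intensity mixture for one (cell line, marker).

    All conditions are pooled so the threshold is global per cell line and
    marker. Cells with nonpositive intensity are dropped with a log entry.
    """
    sub = table if cell_line is None else table[table["cell_line"] == cell_line]
    raw = sub[marker].to_numpy(dtype=float)
    positive = raw > 0
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info("%s/%s: dropped %d cells with nonpositive intensity",
                    cell_line, marker, n_dropped)
    x = _log_transform(raw[positive], log_base)
    if x.size < 50:
        raise DataError(f"fewer than 50 cells pooled for {cell_line}/{marker}")
    fit = fit_gmm_1d(x, seed=seed)
    if fit.boundary is None or not (x.min() <= fit.boundary <= x.max()):
        logger.warning("%s/%s: boundary outside data range; using posterior-0.5 crossing",
                       cell_line, marker)
        threshold = gmm_boundary(fit)
    else:
        threshold = fit.boundary
    return GateEntry(cell_line=cell_line or "all", marker=marker, fit=fit,
                     threshold=threshold, log_base=log_base, n_cells=int(x.size))


def fraction_high(table: pd.DataFrame, gate: GateEntry) -> pd.DataFrame:
    """Percent of cells above the gate per (condition, replicate) and pooled.

    A cell is high iff its log-intensity is strictly above the threshold.
    Returns rows with replicate='pooled' for per-condition totals.
    """
    sub = table[table["cell_line"] == gate.cell_line] if "cell_line" in table.columns else table
    sub = sub[sub[gate.marker] > 0]
    logx = _log_transform(sub[gate.marker].to_numpy(dtype=float), gate.log_base)
    high = logx > gate.threshold
    df = pd.DataFrame({"condition": sub["condition"].to_numpy(),
                       "replicate": sub["replicate"].to_numpy(), "high": high})
    rows = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        if len(grp) == 0:
            continue
        rows.append({"condition": cond, "replicate": str(rep),
                     "n_cells": len(grp), "pct_high": 100.0 * grp["high"].mean()})
    for cond, grp in df.groupby("condition"):
        rows.append({"condition": cond, "replicate": "pooled",
                     "n_cells": len(grp), "pct_high": 100.0 * grp["high"].mean()})
    return pd.DataFrame(rows)


def quadrant_fractions(table: pd.DataFrame, gate_x: GateEntry, gate_y: GateEntry,
                       sample_n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """2x2 quadrant percentages per condition (computed on all cells).

    ``sample_n`` only selects cells for a display export (column ``sampled``);
    the percentages always use every cell.
    """
    sub = table
    if "cell_line" in table.columns and gate_x.cell_line != "all":
        sub = table[table["cell_line"] == gate_x.cell_line]
    ok = (sub[gate_x.marker] > 0) & (sub[gate_y.marker] > 0)
    sub = sub[ok]
    hx = _log_transform(sub[gate_x.marker].to_numpy(float), gate_x.log_base) > gate_x.threshold
    hy = _log_transform(sub[gate_y.marker].to_numpy(float), gate_y.log_base) > gate_y.threshold
    quad = np.where(hx, np.where(hy, "high_high", "high_low"),
                    np.where(hy, "low_high", "low_low"))
    rows = []
    for cond, idx in pd.Series(range(len(sub)), index=sub.index).groupby(sub["condition"]).groups.items():
        mask = sub["condition"] == cond
        q = quad[mask.to_numpy()]
        n = q.size
        row = {"condition": cond, "n_cells": n}
        for name in ("low_low", "low_high", "high_low", "high_high"):
            row[f"pct_{name}"] = 100.0 * float((q == name).sum()) / n
        rows.append(row)
    return pd.DataFrame(rows)


def welch_replicate_test(summary: pd.DataFrame, value_column: str,
                         control_condition: str,
                         epsilon: float = 1e-12) -> pd.DataFrame:
    """Two-sided Welch t-test of replicate-level values vs the control condition.

    Zero within-group variance is guarded by adding ``epsilon`` to each
    variance so identical-but-shifted replicates still yield a finite test.
    """
    reps = summary[summary["replicate"] != "pooled"]
    ctrl = reps.loc[reps["condition"] == control_condition, value_column].to_numpy(float)
    if ctrl.size < 2:
        raise DataError("need >=2 control replicates")
    rows = []
    for cond, grp in reps.groupby("condition"):
        if cond == control_condition:
            continue
        x = grp[value_column].to_numpy(float)
        if x.size < 2:
            raise DataError(f"need >=2 replicates for condition {cond}")
        rows.append({"condition": cond, "control": control_condition,
                     **_welch(x, ctrl, epsilon)})
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray, epsilon: float) -> dict:
    va = a.var(ddof=1) + epsilon
    vb = b.var(ddof=1) + epsilon
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return {"t": t, "df": df, "p": p}


def normalized_cell_count(table: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Replicate nuclei counts divided by the mean control count per cell line."""
    counts = (table.groupby(["cell_line", "condition", "replicate"])
              .size().rename("n_cells").reset_index())
    rows = []
    for cl, grp in counts.groupby("cell_line"):
        ctrl = grp.loc[grp["condition"] == control_condition, "n_cells"]
        if ctrl.empty:
            raise DataError(f"no control replicates for cell line {cl}")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise DataError(f"zero control cell count for {cl}")
        for _, row in grp.iterrows():
            rows.append({"cell_line": cl, "condition": row["condition"],
                         "replicate": row["replicate"], "n_cells": row["n_cells"],
                         "normalized_count": row["n_cells"] / ctrl_mean})
    return pd.DataFrame(rows)


def delta_regression(deltas_x: np.ndarray, deltas_y: np.ndarray) -> dict:
    """OLS of delta-% y on delta-% x: slope, intercept, R^2."""
    x = np.asarray(deltas_x, dtype=float)
    y = np.asarray(deltas_y, dtype=float)
    if x.size < 3:
        raise DataError("need at least three points")
    if np.var(x) == 0:
        raise DataError("zero variance in x")
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"slope": float(res.slope), "intercept": float(res.intercept), "r2": r2}
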