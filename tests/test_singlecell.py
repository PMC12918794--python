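import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdep.errors import DataError
from chromdep.singlecell import (GateEntry, delta_regression, fraction_high,
                                 normalized_cell_count, pool_and_gate,
                                 quadrant_fractions, welch_replicate_test)
from chromdep.state_classification import GmmFit1D, gmm_boundary
from chromdep.synthetic import gen_singlecell_intensities


def _gate(threshold, marker="m", cell_line="cl"):
    fit = GmmFit1D(weights=(0.5, 0.5), means=(threshold - 1, threshold + 1),
                   sds=(0.3, 0.3), log_likelihood=0.0, boundary=threshold,
                   n_iter=1, converged=True)
    return GateEntry(cell_line=cell_line, marker=marker, fit=fit,
                     threshold=threshold, log_base=10.0, n_cells=100)


def _table(log_values, condition="c", replicate="r1", marker="m", cell_line="cl"):
    return pd.DataFrame({
        "cell_line": cell_line, "condition": condition, "replicate": replicate,
        marker: 10.0 ** np.asarray(log_values, dtype=float),
    })


class TestPoolAndGate:
    def test_balanced_lognormal_mixture(self):
        rng = np.random.default_rng(42)
        n = 5000
        comp = rng.random(n) < 0.5
        logx = np.where(comp, rng.normal(2.0, 0.15, n), rng.normal(1.0, 0.15, n))
        table = _table(logx)
        gate = pool_and_gate(table, "m", cell_line="cl", seed=0)
        assert gate.threshold == pytest.approx(1.5, abs=0.05)

    def test_pooled_across_conditions(self):
        rng = np.random.default_rng(1)
        t1 = _table(rng.normal(1.0, 0.1, 200), condition="A")
        t2 = _table(rng.normal(2.0, 0.1, 200), condition="B")
        table = pd.concat([t1, t2], ignore_index=True)
        gate = pool_and_gate(table, "m", cell_line="cl", seed=0)
        # threshold derived from the pooled fit, independent of condition
        assert 1.2 < gate.threshold < 1.8
        assert gate.n_cells == 400

    def test_density_equality_at_threshold(self):
        rng = np.random.default_rng(2)
        logx = np.concatenate([rng.normal(1.0, 0.2, 500), rng.normal(2.5, 0.2, 500)])
        gate = pool_and_gate(_table(logx), "m", cell_line="cl", seed=0)
        d0 = gate.fit.component_density(np.array([gate.threshold]), 0)[0]
        d1 = gate.fit.component_density(np.array([gate.threshold]), 1)[0]
        assert abs(d0 - d1) < 1e-10

    def test_nonpositive_intensities_dropped(self):
        rng = np.random.default_rng(3)
        table = _table(np.concatenate([rng.normal(1, 0.2, 100),
                                       rng.normal(2, 0.2, 100)]))
        table.loc[:4, "m"] = -1.0
        gate = pool_and_gate(table, "m", cell_line="cl", seed=0)
        assert gate.n_cells == 195

    def test_too_few_cells_rejected(self):
        with pytest.raises(DataError):
            pool_and_gate(_table([1.0] * 10), "m", cell_line="cl")

    def test_scale_invariance_of_fractions(self):
        rng = np.random.default_rng(4)
        logx = np.concatenate([rng.normal(1, 0.15, 400), rng.normal(2, 0.15, 400)])
        t1 = _table(logx)
        t2 = t1.copy()
        t2["m"] = t2["m"] * 1000.0  # x1000 shifts log10 by 3
        g1 = pool_and_gate(t1, "m", cell_line="cl", seed=0)
        g2 = pool_and_gate(t2, "m", cell_line="cl", seed=0)
        assert g2.threshold == pytest.approx(g1.threshold + 3.0, abs=0.01)
        f1 = fraction_high(t1, g1)
        f2 = fraction_high(t2, g2)
        p1 = f1[f1.replicate == "pooled"]["pct_high"].iloc[0]
        p2 = f2[f2.replicate == "pooled"]["pct_high"].iloc[0]
        assert p1 == pytest.approx(p2, abs=0.5)


class TestFractionHigh:
    def test_half_above(self):
        table = _table([0.5, 1.5, 2.0, 0.8])
        out = fraction_high(table, _gate(1.0))
        assert out[out.replicate == "pooled"]["pct_high"].iloc[0] == pytest.approx(50.0)

    def test_all_below(self):
        out = fraction_high(_table([0.1, 0.2, 0.3]), _gate(1.0))
        assert out["pct_high"].iloc[0] == pytest.approx(0.0)

    def test_exact_threshold_counted_low(self):
        out = fraction_high(_table([1.0, 2.0]), _gate(1.0))
        assert out[out.replicate == "pooled"]["pct_high"].iloc[0] == pytest.approx(50.0)

    def test_pooled_is_weighted_mean_of_replicates(self):
        t1 = _table([0.5, 1.5, 1.6], replicate="r1")
        t2 = _table([0.5], replicate="r2")
        table = pd.concat([t1, t2], ignore_index=True)
        out = fraction_high(table, _gate(1.0))
        reps = out[out.replicate != "pooled"]
        pooled = out[out.replicate == "pooled"]["pct_high"].iloc[0]
        weighted = (reps["pct_high"] * reps["n_cells"]).sum() / reps["n_cells"].sum()
        assert pooled == pytest.approx(weighted)


class TestQuadrants:
    def _two_marker_table(self, log_x, log_y, condition="c"):
        return pd.DataFrame({
            "cell_line": "cl", "condition": condition, "replicate": "r1",
            "mx": 10.0 ** np.asarray(log_x), "my": 10.0 ** np.asarray(log_y),
        })

    def test_one_cell_per_quadrant(self):
        table = self._two_marker_table([0.5, 0.5, 1.5, 1.5], [0.5, 1.5, 0.5, 1.5])
        out = quadrant_fractions(table, _gate(1.0, "mx"), _gate(1.0, "my"))
        for q in ("pct_low_low", "pct_low_high", "pct_high_low", "pct_high_high"):
            assert out[q].iloc[0] == pytest.approx(25.0)

    def test_quadrants_sum_100(self, rng):
        table = self._two_marker_table(rng.normal(1, 0.5, 500), rng.normal(1, 0.5, 500))
        out = quadrant_fractions(table, _gate(1.0, "mx"), _gate(1.0, "my"))
        total = sum(out[f"pct_{q}"].iloc[0] for q in
                    ("low_low", "low_high", "high_low", "high_high"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_coupled_markers_empty_off_diagonal(self):
        table, _ = gen_singlecell_intensities(
            ["cl"], ["mx", "my"], ["c"], n_replicates=1, n_cells=400,
            mixture_params={("cl", "c", "mx"): {"high_fraction": 0.5}},
            coupling={"my": ("mx", 1.0)}, seed=5)
        gx = pool_and_gate(table, "mx", cell_line="cl", seed=0)
        gy = pool_and_gate(table, "my", cell_line="cl", seed=0)
        out = quadrant_fractions(table, gx, gy)
        assert out["pct_low_high"].iloc[0] < 2.0
        assert out["pct_high_low"].iloc[0] < 2.0


class TestWelch:
    def _summary(self, ctrl_vals, treat_vals):
        rows = []
        for i, v in enumerate(ctrl_vals):
            rows.append({"condition": "ctrl", "replicate": f"r{i}", "pct_high": v})
        for i, v in enumerate(treat_vals):
            rows.append({"condition": "treat", "replicate": f"r{i}", "pct_high": v})
        return pd.DataFrame(rows)

    def test_identical_replicates(self):
        out = welch_replicate_test(self._summary([1, 2, 3], [1, 2, 3]),
                                   "pct_high", "ctrl")
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        out = welch_replicate_test(self._summary([1, 1, 1], [2, 2, 2]),
                                   "pct_high", "ctrl")
        assert out["p"].iloc[0] < 0.01

    def test_matches_scipy_welch(self, rng):
        a = rng.normal(0, 1, size=3)
        b = rng.normal(1, 2, size=3)
        out = welch_replicate_test(self._summary(b, a), "pct_high", "ctrl")
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert out["t"].iloc[0] == pytest.approx(t_ref, abs=1e-8)
        assert out["p"].iloc[0] == pytest.approx(p_ref, abs=1e-8)
        # Welch-Satterthwaite df oracle
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert out["df"].iloc[0] == pytest.approx(df, rel=1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(DataError):
            welch_replicate_test(self._summary([1, 2, 3], [5]), "pct_high", "ctrl")


class TestNormalizedCellCount:
    def _count_table(self, counts_by_cond_rep):
        frames = []
        for (cond, rep), n in counts_by_cond_rep.items():
            frames.append(pd.DataFrame({
                "cell_line": "cl", "condition": cond, "replicate": rep,
                "m": np.ones(n),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_arithmetic(self):
        table = self._count_table({("ctrl", "r1"): 900, ("ctrl", "r2"): 1000,
                                   ("ctrl", "r3"): 1100, ("treat", "r1"): 500})
        out = normalized_cell_count(table, "ctrl")
        treat = out[out.condition == "treat"]["normalized_count"].iloc[0]
        assert treat == pytest.approx(0.5)

    def test_control_averages_to_one(self):
        table = self._count_table({("ctrl", "r1"): 800, ("ctrl", "r2"): 1200})
        out = normalized_cell_count(table, "ctrl")
        assert out[out.condition == "ctrl"]["normalized_count"].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        t1 = self._count_table({("ctrl", "r1"): 100, ("treat", "r1"): 50})
        t2 = self._count_table({("ctrl", "r1"): 200, ("treat", "r1"): 100})
        o1 = normalized_cell_count(t1, "ctrl")
        o2 = normalized_cell_count(t2, "ctrl")
        np.testing.assert_allclose(o1["normalized_count"], o2["normalized_count"])


class TestDeltaRegression:
    def test_collinear(self):
        out = delta_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_constant_y(self):
        out = delta_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert out["r2"] == pytest.approx(0.0)

    def test_normal_equations_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        out = delta_regression(x, y)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert out["intercept"] == pytest.approx(beta[0], abs=1e-12)
        assert out["slope"] == pytest.approx(beta[1], abs=1e-12)
        assert out["r2"] == pytest.approx(r2, abs=1e-12)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(DataError):
            delta_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_fraction_recovery_from_generator():
    params = {("cl", "A", "m"): {"high_fraction": 0.85},
              ("cl", "B", "m"): {"high_fraction": 0.25}}
    table, _ = gen_singlecell_intensities(["cl"], ["m"], ["A", "B"],
                                          n_replicates=3, n_cells=3000,
                                          mixture_params=params, seed=9)
    gate = pool_and_gate(table, "m", cell_line="cl", seed=0)
    out = fraction_high(table, gate)
    a = out[(out.condition == "A") & (out.replicate == "pooled")]["pct_high"].iloc[0]
    b = out[(out.condition == "B") & (out.replicate == "pooled")]["pct_high"].iloc[0]
    assert a == pytest.approx(85.0, abs=3.0)
    assert b == pytest.approx(25.0, abs=3.0)
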