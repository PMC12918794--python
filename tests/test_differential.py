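import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromdep.differential import (ModerationParams, add_fdr, bh_adjust,
                                   call_enriched, differential_table,
                                   fit_one_vs_rest, moderate_variances,
                                   moderated_t, rank_sum_compare, ward_cluster,
                                   zscore_rows)
from chromdep.errors import DataError
from chromdep.io_model import AnalysisConfig


def _matrix(values, features=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"f{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=features,
                        columns=[f"cl{j}" for j in range(values.shape[1])])


class TestFitOneVsRest:
    def test_mean_of_means_contrast(self):
        # lineage A mean 0.8; others mean 0.2 and 0.4 -> logFC_A = 0.8 - 0.3
        vals = [[0.8, 0.8, 0.2, 0.2, 0.4, 0.4]]
        labels = ["A", "A", "B", "B", "C", "C"]
        fit = fit_one_vs_rest(_matrix(vals), pd.Series(labels))
        assert fit.logfc.loc["f0", "A"] == pytest.approx(0.5)
        assert fit.logfc.loc["f0", "B"] == pytest.approx(0.2 - 0.6)

    def test_constant_groups(self):
        vals = [[0.3] * 6]
        fit = fit_one_vs_rest(_matrix(vals), pd.Series(["A", "A", "B", "B", "C", "C"]))
        assert fit.logfc.loc["f0"].abs().max() == pytest.approx(0.0)
        assert fit.s2.loc["f0"] == pytest.approx(0.0)

    def test_against_normal_equations_oracle(self, rng):
        # 3 lineages x 4 lines x 50 genes; oracle = explicit OLS on the
        # no-intercept group design with the one-vs-rest contrast vector
        labels = np.repeat(["A", "B", "C"], 4)
        X = rng.normal(size=(50, 12))
        mat = _matrix(X)
        fit = fit_one_vs_rest(mat, pd.Series(labels))
        design = np.stack([(labels == lin).astype(float) for lin in ["A", "B", "C"]], axis=1)
        XtX_inv = np.linalg.inv(design.T @ design)
        for g in range(50):
            beta = XtX_inv @ design.T @ X[g]
            resid = X[g] - design @ beta
            s2 = resid @ resid / (12 - 3)
            assert fit.s2.iloc[g] == pytest.approx(s2, abs=1e-10)
            for j, lin in enumerate(["A", "B", "C"]):
                contrast = np.full(3, -0.5)
                contrast[j] = 1.0
                assert fit.logfc.iloc[g, j] == pytest.approx(contrast @ beta, abs=1e-10)
                v = contrast @ XtX_inv @ contrast
                assert fit.v.loc[lin] == pytest.approx(v, abs=1e-10)

    def test_pooled_rest_mean(self):
        vals = [[1.0, 1.0, 0.0, 0.0, 0.0, 2.0, 2.0]]
        labels = pd.Series(["A", "A", "B", "B", "B", "C", "C"])
        fit = fit_one_vs_rest(_matrix(vals), labels, rest_mean="pooled")
        # pooled rest of A: (0+0+0+2+2)/5 = 0.8
        assert fit.logfc.loc["f0", "A"] == pytest.approx(0.2)
        assert fit.v.loc["A"] == pytest.approx(1 / 2 + 1 / 5)

    def test_singleton_lineage_rejected(self):
        with pytest.raises(DataError):
            fit_one_vs_rest(_matrix([[1, 2, 3]]), pd.Series(["A", "A", "B"]))


class TestModerateVariances:
    def test_d0_zero_no_shrinkage(self):
        s2 = pd.Series([1.0, 2.0, 3.0])
        post = ModerationParams(0.0, 5.0).posterior(s2, df=10)
        pd.testing.assert_series_equal(post, s2)

    def test_d0_inf_full_shrinkage(self):
        s2 = pd.Series([1.0, 2.0, 3.0])
        post = ModerationParams(math.inf, 5.0).posterior(s2, df=10)
        assert (post == 5.0).all()

    def test_parameter_recovery(self):
        # true prior: d0=8, s0^2=1; observed s2 ~ sigma_g^2 chi2_df/df, df=16
        rng = np.random.default_rng(2024)
        n, d0_true, s0_true, df = 5000, 8.0, 1.0, 16
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        params, post = moderate_variances(pd.Series(s2), df=df)
        assert 6.0 <= params.d0 <= 10.0
        assert 0.9 <= params.s0_sq <= 1.1
        # posterior lies between prior and observed
        assert ((post - s2) * (params.s0_sq - s2) >= -1e-12).all()

    def test_homogeneous_variances_give_infinite_d0(self):
        rng = np.random.default_rng(5)
        df = 50
        s2 = rng.chisquare(df, size=3000) / df  # no gene-level heterogeneity
        params, _ = moderate_variances(pd.Series(s2), df=df)
        assert params.d0 > 1e4 or math.isinf(params.d0)

    def test_all_zero_errors(self):
        with pytest.raises(DataError):
            moderate_variances(pd.Series([0.0, 0.0]), df=4)


class TestModeratedT:
    def test_zero_logfc(self):
        mat = _matrix([[0.5, 0.5, 0.5, 0.5, 0.1, 0.9, 0.3, 0.7]])
        labels = pd.Series(["A"] * 4 + ["B"] * 4)
        fit = fit_one_vs_rest(mat, labels)
        table = moderated_t(fit, ModerationParams(0.0, 1.0))
        row = table[(table.feature == "f0") & (table.lineage == "A")].iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_d0_zero_equals_classical_t(self, rng):
        a = rng.normal(0.0, 1.0, size=6)
        b = rng.normal(0.5, 1.0, size=8)
        mat = _matrix([np.concatenate([a, b])])
        labels = pd.Series(["A"] * 6 + ["B"] * 8)
        fit = fit_one_vs_rest(mat, labels)
        table = moderated_t(fit, ModerationParams(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        row = table[(table.feature == "f0") & (table.lineage == "A")].iloc[0]
        assert abs(row["t"]) == pytest.approx(abs(t_ref), abs=1e-10)
        assert row["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_null_type_one_error(self):
        # fraction of p < 0.05 on pure-null data, averaged over reps
        fracs = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            mat = _matrix(rng.normal(size=(500, 50)))
            labels = pd.Series(np.repeat([f"L{i}" for i in range(5)], 10))
            fit = fit_one_vs_rest(mat, labels)
            mod, _ = moderate_variances(fit.s2, fit.df_residual)
            table = moderated_t(fit, mod)
            fracs.append((table["p"] < 0.05).mean())
        assert 0.035 <= np.mean(fracs) <= 0.065


class TestBhAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_bh_properties(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallEnriched:
    @pytest.fixture
    def config(self):
        return AnalysisConfig()

    def _table(self, logfc, fdr):
        return pd.DataFrame({"feature": ["x"], "lineage": ["A"],
                             "logFC": [logfc], "t": [1.0], "p": [0.01],
                             "FDR": [fdr]})

    def test_gene_enriched(self, config):
        assert call_enriched(self._table(0.15, 0.01), "gene", config)["enriched"].iloc[0]

    def test_gene_below_lfc(self, config):
        assert not call_enriched(self._table(0.09, 0.001), "gene", config)["enriched"].iloc[0]

    def test_gene_lfc_boundary_inclusive(self, config):
        assert call_enriched(self._table(0.10, 0.05), "gene", config)["enriched"].iloc[0]

    def test_complex_rule(self, config):
        assert call_enriched(self._table(0.02, 0.08), "complex", config)["enriched"].iloc[0]
        assert not call_enriched(self._table(0.0, 0.08), "complex", config)["enriched"].iloc[0]

    def test_unknown_level(self, config):
        with pytest.raises(ValueError):
            call_enriched(self._table(0.1, 0.01), "pathway", config)


class TestZscoreRows:
    def test_simple_row(self):
        z = zscore_rows(_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        z = zscore_rows(_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        assert list(z.index) == ["f1"]

    def test_mean_zero_sd_one(self, rng):
        z = zscore_rows(_matrix(rng.normal(size=(20, 15))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


def _lance_williams_ward(points):
    """Independent ward.D2 oracle on 1-D points via the Lance-Williams update."""
    clusters = {i: [float(p)] for i, p in enumerate(points)}
    d2 = {}
    for i in clusters:
        for j in clusters:
            if i < j:
                d2[(i, j)] = (clusters[i][0] - clusters[j][0]) ** 2
    sizes = {i: 1 for i in clusters}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        (a, b), dmin = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, math.sqrt(dmin)))
        new = next_id
        next_id += 1
        for c in list(clusters):
            if c in (a, b):
                continue
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            na, nb, nc = sizes[a], sizes[b], sizes[c]
            n = na + nb + nc
            d2[(c, new)] = ((na + nc) * d2[key_ac] + (nb + nc) * d2[key_bc]
                            - nc * dmin) / n
        for key in list(d2):
            if a in key or b in key:
                del d2[key]
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        sizes[new] = sizes.pop(a) + sizes.pop(b)
    return merges


class TestWardCluster:
    def test_hand_case_0_1_10(self):
        mat = _matrix([[0.0], [1.0], [10.0]], features=["a", "b", "c"])
        merges, _ = ward_cluster(mat, axis="rows")
        assert merges["height"].iloc[0] == pytest.approx(1.0)
        assert merges["height"].iloc[1] == pytest.approx(math.sqrt(361 / 3))
        oracle = _lance_williams_ward([0.0, 1.0, 10.0])
        np.testing.assert_allclose(merges["height"], [h for _, _, h in oracle])

    def test_identical_points_merge_at_zero(self):
        mat = _matrix([[3.0, 3.0], [3.0, 3.0]], features=["a", "b"])
        merges, _ = ward_cluster(mat)
        assert merges["height"].iloc[0] == pytest.approx(0.0)

    def test_permutation_invariant_heights(self, rng):
        X = rng.normal(size=(8, 4))
        mat = _matrix(X)
        perm = rng.permutation(8)
        merges1, _ = ward_cluster(mat)
        merges2, _ = ward_cluster(mat.iloc[perm])
        np.testing.assert_allclose(sorted(merges1["height"]),
                                   sorted(merges2["height"]), atol=1e-10)

    def test_oracle_on_random_1d(self, rng):
        pts = rng.normal(size=6)
        merges, _ = ward_cluster(_matrix(pts[:, None]))
        oracle = _lance_williams_ward(list(pts))
        np.testing.assert_allclose(sorted(merges["height"]),
                                   sorted(h for _, _, h in oracle), atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(_matrix([[np.nan], [1.0]]))


class TestRankSum:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank splits; observed is the most extreme -> p = 2/6
        _, p = rank_sum_compare([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        _, p = rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_large_shift(self, rng):
        a = rng.normal(0, 1, size=50)
        b = rng.normal(5, 1, size=50)
        _, p = rank_sum_compare(a, b)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            rank_sum_compare([], [1.0])


class TestDifferentialTable:
    def test_planted_gene_flagged(self, rng):
        labels = pd.Series(np.repeat(["A", "B", "C"], 10))
        X = rng.normal(0.3, 0.05, size=(40, 30))
        X[0, :10] += 0.3  # plant in lineage A
        table = differential_table(_matrix(X), labels, "gene", AnalysisConfig())
        row = table[(table.feature == "f0") & (table.lineage == "A")].iloc[0]
        assert row["enriched"]
        others = table[(table.feature != "f0") & table.enriched]
        assert len(others) == 0

    def test_fdr_within_contrast(self, rng):
        labels = pd.Series(np.repeat(["A", "B"], 5))
        X = rng.normal(size=(20, 10))
        table = differential_table(_matrix(X), labels, "gene", AnalysisConfig())
        for _, grp in table.groupby("lineage"):
            np.testing.assert_allclose(grp["FDR"], bh_adjust(grp["p"].to_numpy()))
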