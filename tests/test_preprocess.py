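"""Normalization, imputation, residualization and differential statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signet import preprocess as pp
from signet.types import OmicsView

from conftest import make_view


def counts_view(data, samples=None):
    mat = pd.DataFrame(data, index=samples or [f"s{i}" for i in
                                               range(len(data))])
    mat.columns = [f"g{j}" for j in range(mat.shape[1])]
    return make_view(mat.astype(np.int64), label="mrna")


class TestCpmFilter:
    def test_zero_gene_dropped_low_gene_kept(self):
        v = counts_view([[0, 1, 500], [0, 0, 500]])
        # lib sizes 501/500; CPM of g1 in s0 = 1/501*1e6 ~ 1996 > 2
        out = pp.cpm_filter(v, threshold=2.0)
        assert list(out.matrix.columns) == ["g1", "g2"]

    def test_hand_computed_cpm_boundary(self):
        mat = pd.DataFrame({"g0": [1, 0], "g1": [999, 1000]},
                           index=["s0", "s1"])
        v = make_view(mat.astype(np.int64), label="mrna")
        out = pp.cpm_filter(v, threshold=2.0)  # CPM g0 = (1000, 0)
        assert "g0" in out.matrix.columns

    def test_infinite_threshold_warns_empty(self):
        v = counts_view([[5, 5], [5, 5]])
        with pytest.warns(UserWarning):
            out = pp.cpm_filter(v, threshold=np.inf)
        assert out.matrix.shape[1] == 0

    def test_zero_library_errors(self):
        v = counts_view([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="all-zero"):
            pp.cpm_filter(v)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        v = counts_view([[10, 20, 30, 40], [10, 20, 30, 40]])
        f = pp.effective_library_sizes(v)
        assert np.allclose(f, 1.0)

    def test_pure_rescaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 1000, size=50)
        v = counts_view([base, 2 * base])
        f = pp.effective_library_sizes(v)
        assert np.allclose(np.log(f), 0.0, atol=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        v = counts_view(rng.integers(0, 500, size=(5, 80)))
        f = pp.effective_library_sizes(v)
        assert np.isclose(np.exp(np.log(f).mean()), 1.0)

    def test_all_zero_sample_named(self):
        v = counts_view([[0, 0, 0], [1, 2, 3]])
        with pytest.raises(ValueError, match="s0"):
            pp.effective_library_sizes(v)


class TestLogCpm:
    def test_direct_arithmetic(self):
        mat = pd.DataFrame({"g0": [0], "g1": [10**6 - 1]}, index=["s0"])
        v = make_view(mat.astype(np.int64), label="mrna")
        out = pp.log_cpm(v, pd.Series({"s0": 1.0}), prior_count=0.5)
        expected = np.log2(0.5 / (10**6 + 1) * 1e6)
        assert np.isclose(out.loc["s0", "g0"], expected, atol=1e-9)
        assert abs(out.loc["s0", "g0"] + 1.0) < 1e-4

    def test_doubling_near_invariant_for_moderate_counts(self):
        rng = np.random.default_rng(5)
        base = rng.integers(50, 2000, size=100)
        v1 = counts_view([base])
        v2 = counts_view([2 * base])
        l1 = pp.log_cpm(v1).to_numpy()
        l2 = pp.log_cpm(v2).to_numpy()
        assert np.abs(l1 - l2).max() < 0.01

    def test_monotone_in_count(self):
        v = counts_view([[1, 5, 25, 125]])
        out = pp.log_cpm(v).to_numpy().ravel()
        assert (np.diff(out) > 0).all()


class TestQcImpute:
    def test_qc_boundary_inclusive_at_threshold(self):
        mat = pd.DataFrame(np.ones((3, 60)),
                           index=["s0", "s1", "s2"])
        mat.iloc[0, :11] = np.nan  # 49 quantified -> dropped
        mat.iloc[1, :10] = np.nan  # 50 quantified -> kept
        v = make_view(mat)
        out = pp.qc_filter_samples(v, min_quantified=50)
        assert list(out.matrix.index) == ["s1", "s2"]

    def test_impute_condition_mean_and_threshold(self):
        mat = pd.DataFrame({"f0": [1.0, 2.0, 3.0, np.nan],
                            "f1": [1.0, 2.0, np.nan, np.nan]},
                           index=[f"s{i}" for i in range(4)])
        v = make_view(mat)  # all samples share one condition
        out = pp.impute_within_condition(v, min_quantified=3)
        assert out.matrix.loc["s3", "f0"] == 2.0
        assert np.isnan(out.matrix.loc["s2", "f1"])  # only 2 observed

    def test_impute_identity_when_complete(self):
        mat = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        v = make_view(mat)
        out = pp.impute_within_condition(v)
        assert out.matrix.equals(mat)

    def test_filters_commute_with_sample_reordering(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(6, 80)),
                           index=[f"s{i}" for i in range(6)])
        mat[mat > 1.2] = np.nan
        v = make_view(mat)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        v_perm = make_view(mat.loc[perm])
        a = pp.impute_within_condition(pp.qc_filter_samples(v, 40))
        b = pp.impute_within_condition(pp.qc_filter_samples(v_perm, 40))
        assert np.allclose(a.matrix.sort_index().to_numpy(),
                           b.matrix.sort_index().to_numpy(),
                           equal_nan=True, atol=1e-12)


class TestCenterScale:
    def test_constant_feature_zeroed(self):
        # sample medians are equal, so f0 stays constant after centering
        mat = pd.DataFrame({"f0": [5.0, 5.0, 5.0], "f1": [1.0, 2.0, 4.0],
                            "f2": [9.0, 8.0, 6.0]})
        v = make_view(mat)
        out = pp.median_center_scale(v)
        assert (out.matrix["f0"] == 0).all()
        assert np.isclose(out.matrix["f1"].std(ddof=1), 1.0)

    def test_sample_median_zero_after_centering(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(5, 9)))
        centered = mat.sub(mat.median(axis=1), axis=0)
        assert np.allclose(centered.median(axis=1), 0.0)


class TestNetPhosphorylation:
    def _views(self, phospho_vals, protein_vals):
        samples = [f"s{i}" for i in range(len(protein_vals))]
        prot = make_view(pd.DataFrame({"P1": protein_vals}, index=samples))
        ph = pd.DataFrame({"P1_S5": phospho_vals}, index=samples)
        feat = pd.DataFrame({"protein": ["P1"], "position": [5]},
                            index=["P1_S5"])
        phospho = OmicsView("phospho", ph, prot.sample_meta, feature_meta=feat)
        return phospho, prot

    def test_identical_gives_zero_residuals(self):
        ph, prot = self._views([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        out = pp.net_phosphorylation(ph, prot)
        assert np.allclose(out.matrix["P1_S5"], 0.0, atol=1e-12)

    def test_orthogonal_gives_centered_values(self):
        ph, prot = self._views([1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0])
        out = pp.net_phosphorylation(ph, prot)
        assert np.allclose(out.matrix["P1_S5"], [1, -1, 1, -1], atol=1e-12)

    def test_residuals_orthogonal_to_regressor(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(size=20)
        ph, prot = self._views(list(y), list(x))
        out = pp.net_phosphorylation(ph, prot)
        r = np.corrcoef(out.matrix["P1_S5"], x)[0, 1]
        assert abs(r) < 1e-8
        assert out.feature_meta.loc["P1_S5", "net_flag"] == "ok"

    def test_unmatched_site_flagged_and_centered(self):
        samples = ["s0", "s1", "s2"]
        prot = make_view(pd.DataFrame({"P9": [1.0, 2.0, 3.0]}, index=samples))
        ph = pd.DataFrame({"PX_S1": [4.0, 5.0, 6.0]}, index=samples)
        feat = pd.DataFrame({"protein": ["PX"]}, index=["PX_S1"])
        phospho = OmicsView("phospho", ph, prot.sample_meta, feature_meta=feat)
        out = pp.net_phosphorylation(phospho, prot)
        assert out.feature_meta.loc["PX_S1", "net_flag"] == "unmatched"
        assert np.allclose(out.matrix["PX_S1"], [-1, 0, 1])


def test_aggregate_duplicate_sites_mean():
    samples = ["s0", "s1"]
    mat = pd.DataFrame([[1.0, 3.0, 7.0], [5.0, 7.0, 7.0]], index=samples,
                       columns=["A_S1", "A_S1", "B_S2"])
    meta = make_view(pd.DataFrame(np.zeros((2, 1)), index=samples)).sample_meta
    v = OmicsView("phospho", mat, meta)
    out = pp.aggregate_duplicate_sites(v)
    assert list(out.matrix.columns) == ["A_S1", "B_S2"]
    assert out.matrix["A_S1"].tolist() == [2.0, 6.0]


class TestDifferentialAbundance:
    def test_identical_groups_null(self):
        mat = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                           index=[f"s{i}" for i in range(6)])
        v = make_view(mat)
        res = pp.differential_abundance(v, (["s0", "s1", "s2"],
                                            ["s3", "s4", "s5"]))
        assert res.loc["f0", "lfc"] == 0
        assert res.loc["f0", "p"] == pytest.approx(1.0)

    def test_zero_variance_degenerate_rule(self):
        mat = pd.DataFrame({"f0": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]},
                           index=[f"s{i}" for i in range(6)])
        v = make_view(mat)
        res = pp.differential_abundance(v, (["s3", "s4", "s5"],
                                            ["s0", "s1", "s2"]))
        assert res.loc["f0", "p"] == 0.0
        assert res.loc["f0", "flag"] == "degenerate"
        assert res.loc["f0", "lfc"] == 1.0

    def test_null_simulation_fdr_control(self):
        rng = np.random.default_rng(9)
        frac = []
        for _ in range(25):
            mat = pd.DataFrame(rng.normal(size=(8, 400)))
            v = make_view(mat)
            res = pp.differential_abundance(
                v, (list(mat.index[:4]), list(mat.index[4:])))
            frac.append((res["adj_p"] < 0.05).mean())
        assert np.mean(frac) <= 0.05

    def test_insufficient_observations_flagged(self):
        mat = pd.DataFrame({"f0": [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]},
                           index=[f"s{i}" for i in range(6)])
        v = make_view(mat)
        res = pp.differential_abundance(v, (["s0", "s1", "s2"],
                                            ["s3", "s4", "s5"]))
        assert res.loc["f0", "flag"] == "insufficient"
        assert np.isnan(res.loc["f0", "p"])


class TestAnovaSelect:
    def _grouped_view(self, data, groups):
        mat = pd.DataFrame(data)
        mat.index = [f"s{i}" for i in range(mat.shape[0])]
        v = make_view(mat, treatment=groups)
        return v

    def test_constant_feature_excluded(self):
        v = self._grouped_view(
            {"f0": [1.0] * 12,
             "f1": [0, 0, 0, 3, 3, 3, 0, 0, 0, 0, 0, 0.0]},
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3)
        sel = pp.anova_select(v, fdr_threshold=0.1, effect_threshold=0.5)
        assert "f0" not in sel.features

    def test_strong_feature_retained_at_both_thresholds(self):
        rng = np.random.default_rng(10)
        base = np.array([0, 3, 0, 0]).repeat(3) + rng.normal(0, 0.1, 12)
        v = self._grouped_view({"f0": base},
                               ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3)
        strict = pp.anova_select(v, fdr_threshold=0.001, effect_threshold=1.0,
                                 adjust=False)
        lenient = pp.anova_select(v, fdr_threshold=0.1, effect_threshold=0.5)
        assert "f0" in strict.features and "f0" in lenient.features

    def test_permuted_labels_near_nominal_rate(self):
        rng = np.random.default_rng(11)
        retained = []
        for _ in range(20):
            mat = pd.DataFrame(rng.normal(size=(12, 200)))
            mat.index = [f"s{i}" for i in range(12)]
            groups = list(rng.permutation(["a"] * 3 + ["b"] * 3 + ["c"] * 3
                                          + ["d"] * 3))
            v = make_view(mat, treatment=groups)
            sel = pp.anova_select(v, fdr_threshold=0.05, effect_threshold=-1,
                                  adjust=False)
            retained.append(len(sel.features) / 200)
        assert np.mean(retained) < 2 * 0.05

    def test_single_group_errors(self):
        v = self._grouped_view({"f0": [1.0, 2.0, 3.0]}, ["a", "a", "a"])
        with pytest.raises(ValueError):
            pp.anova_select(v)


class TestBH:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_closed_form(self, pvals):
        p = pd.Series(pvals)
        adj = pp.bh_adjust(p)
        # independent closed form: adj_(i) = min_{j>=i} min(1, n p_(j) / j)
        n = len(pvals)
        order = np.argsort(p.to_numpy(), kind="mergesort")
        ranked = p.to_numpy()[order]
        stepped = np.minimum.accumulate(
            (n * ranked / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.minimum(stepped, 1.0)
        assert np.allclose(adj.to_numpy()[order], expected, atol=1e-12)
        assert (adj >= p - 1e-12).all()
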