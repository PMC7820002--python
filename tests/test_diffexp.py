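"""QC filter, glog normalization, moderated t, Wilcoxon panel, BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mhelink import diffexp as de
from mhelink.cohort import CohortDesign, generate_gene_matrix
from mhelink.matrix import OmicsMatrix

from conftest import make_matrix


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

class TestQCFilter:
    def _panel(self):
        # 5 MHE + 5 CTRL; three features exercising each rule
        vals = np.array([
            [5, 6, 7, 5, 6, 5, 6, 7, 5, 6],          # clean -> retained
            [5, 6, 7, 5, 6, np.nan, np.nan, 7, 5, 6],  # 40% missing in CTRL
            [0.1, 0.2, 0.1, 0.2, 0.1, 5, 6, 7, 5, 6],  # 50% above lod=1
        ], float)
        return make_matrix(vals, 5, 5, omic="metabolite",
                           feature_ids=["clean", "gappy", "boundary"])

    def test_rules_and_boundaries(self):
        kept, report = de.metabolite_qc_filter(self._panel(), lod=1.0)
        assert report.loc["clean", "retained"]
        # 2/5 = 40% missing in one group violates the <20% rule
        assert not report.loc["gappy", "pass_missing"]
        # exactly 50% of measured values above the LOD counts as passing
        assert report.loc["boundary", "frac_above_lod"] == pytest.approx(0.5)
        assert report.loc["boundary", "retained"]
        assert list(kept.values.index) == ["clean", "boundary"]

    def test_idempotent(self):
        kept, _ = de.metabolite_qc_filter(self._panel(), lod=1.0)
        kept2, rep2 = de.metabolite_qc_filter(kept, lod=1.0)
        pd.testing.assert_frame_equal(kept.values, kept2.values)
        assert rep2["retained"].all()

    def test_all_removed_warns(self):
        m = make_matrix([[np.nan] * 6 + [1] * 5], 6, 5, omic="metabolite")
        with pytest.warns(UserWarning, match="every feature"):
            kept, _ = de.metabolite_qc_filter(m, lod=0.0)
        assert kept.values.shape[0] == 0


# ---------------------------------------------------------------------------
# Variance stabilization
# ---------------------------------------------------------------------------

class TestVST:
    def test_glog_asymptotic_log_behavior(self):
        x = np.array([1e3, 1e5, 1e7])
        assert np.allclose(de.glog2(x, 1.0), np.log2(x), atol=1e-5)

    def test_affine_shift_equalized(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 1000, 60)
        vals = np.column_stack([base, 2 * base + 5])
        cols = ["a", "b"]
        groups = pd.Series(["MHE", "CTRL"], index=cols)
        m = OmicsMatrix(pd.DataFrame(vals, columns=cols), groups, "gene")
        out = de.vst_normalize(m, b=1.0)
        assert np.allclose(out.values["a"], out.values["b"], atol=1e-6)

    def test_sd_trend_flattened(self):
        """SD proportional-to-mean data: trend slope drops >= 80%."""
        rng = np.random.default_rng(1)
        means = np.linspace(20, 2000, 300)
        vals = means[:, None] + rng.standard_normal((300, 12)) * (0.1 * means[:, None] + 2)
        vals = np.clip(vals, 0.1, None)
        m = make_matrix(vals, 6, 6)
        before = de.sd_trend_slope(m.values.to_numpy())
        out = de.vst_normalize(m, calibrate=False)
        after = de.sd_trend_slope(out.values.to_numpy())
        assert abs(after) < 0.2 * abs(before)

    def test_constant_matrix_warns(self):
        m = make_matrix(np.full((3, 11), 7.0), 6, 5)
        with pytest.warns(UserWarning, match="constant"):
            out = de.vst_normalize(m)
        assert out.values.shape == (3, 11)


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

class TestModeratedT:
    def _random_matrix(self, seed=0, n_features=40):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.normal(8, 0.5, (n_features, 11)), 6, 5)

    def test_d0_zero_equals_ordinary_t(self):
        m = self._random_matrix()
        table = de.moderated_ttest(m, prior=(0.0, 1.0))
        x = m.values[m.case_samples].to_numpy()
        y = m.values[m.control_samples].to_numpy()
        ref = stats.ttest_ind(x, y, axis=1)
        assert np.allclose(table["t"], ref.statistic, atol=1e-10)
        assert np.allclose(table["p"], ref.pvalue, atol=1e-10)

    def test_shrinkage_formula(self):
        """s2_post = (d0 s0^2 + dg s2)/(d0 + dg): hand-checked via t."""
        m = self._random_matrix(seed=3, n_features=5)
        d0, s0sq = 4.0, 0.05
        table = de.moderated_ttest(m, prior=(d0, s0sq))
        dg = 9.0
        s2_post = (d0 * s0sq + dg * table["s2"]) / (d0 + dg)
        expected_t = table["logFC"] / np.sqrt(s2_post * (1 / 6 + 1 / 5))
        assert np.allclose(table["t"], expected_t, atol=1e-12)
        # the worked example: dg=9, s2=0.1, d0=4, s0sq=0.05
        assert (4 * 0.05 + 9 * 0.1) / 13 == pytest.approx(0.084615, abs=1e-6)

    def test_matches_independent_empirical_bayes_oracle(self):
        """Frozen reference values from an independent empirical-Bayes
        implementation run on this exact matrix (heterogeneous variances
        drawn from a scaled-inverse-chi-square with d0=4, s0^2=0.05)."""
        rng = np.random.default_rng(7)
        sig2 = 4 * 0.05 / rng.chisquare(4, 30)
        vals = np.array([rng.normal(5, np.sqrt(s), 9) for s in sig2]).round(4)
        m = make_matrix(vals, 5, 4, feature_ids=[f"g{i}" for i in range(30)])
        table = de.moderated_ttest(m)
        assert table.attrs["d0"] == pytest.approx(7.595927663, rel=1e-6)
        assert table.attrs["s0sq"] == pytest.approx(0.06110865321, rel=1e-6)
        assert table.loc["g0", "t"] == pytest.approx(1.279535472, rel=1e-6)
        assert table.loc["g2", "t"] == pytest.approx(-1.246429547, rel=1e-6)
        assert table.loc["g0", "p"] == pytest.approx(0.22067464150, rel=1e-6)

    def test_large_d0_approaches_pooled_z(self):
        m = self._random_matrix(seed=5)
        s0sq = 0.25
        table = de.moderated_ttest(m, prior=(1e6, s0sq))
        expected = table["logFC"] / np.sqrt(s0sq * (1 / 6 + 1 / 5))
        assert np.allclose(table["t"], expected, rtol=1e-3)

    def test_rejects_single_sample_group(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 3)), 1, 2)
        with pytest.raises(ValueError):
            de.moderated_ttest(m)

    def test_null_false_positive_control(self):
        """On a 2000-feature null cohort, q < 0.05 yields at most 2 calls."""
        design = CohortDesign(6, 5, seed=11)
        m = generate_gene_matrix(design, 2000, [])
        table = de.moderated_ttest(de.vst_normalize(m))
        assert int(table["significant"].sum()) <= 2


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum panel
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y):
    """Brute-force enumeration of all group assignments (oracle)."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").statistic
    us = []
    for idx in itertools.combinations(range(len(combined)), n1):
        sel = np.zeros(len(combined), bool)
        sel[list(idx)] = True
        xx, yy = combined[sel], combined[~sel]
        # U statistic by direct pair counting
        us.append(sum((a > b) + 0.5 * (a == b) for a in xx for b in yy))
    us = np.array(us)
    mu = len(x) * len(y) / 2
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


class TestWilcoxonPanel:
    def test_small_example_exact_p(self):
        m = make_matrix([[1, 2, 3, 4, 5]], 3, 2)
        table = de.wilcoxon_panel(m)
        assert table["p"].iloc[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        m = make_matrix([np.concatenate([x, y])], 5, 4)
        table = de.wilcoxon_panel(m)
        assert table["p"].iloc[0] == pytest.approx(exact_ranksum_p(x, y),
                                                   abs=1e-12)

    def test_identical_groups_p_one(self):
        m = make_matrix([[1, 2, 3, 1, 2, 3]], 3, 3)
        table = de.wilcoxon_panel(m)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(2, 1, (4, 11))
        p1 = de.wilcoxon_panel(make_matrix(vals, 6, 5))["p"]
        p2 = de.wilcoxon_panel(make_matrix(np.exp(vals), 6, 5))["p"]
        assert np.allclose(p1, p2, atol=1e-12)

    def test_all_tied_warns_p_one(self):
        m = make_matrix([[3.0] * 11], 6, 5)
        with pytest.warns(UserWarning, match="tied"):
            table = de.wilcoxon_panel(m)
        assert table["p"].iloc[0] == 1.0

    def test_reports_raw_scale_medians(self):
        vals = np.array([[10, 20, 30, 40, 50, 60, 1, 2, 3, 4, 5]], float)
        table = de.wilcoxon_panel(make_matrix(vals, 6, 5))
        assert table["median_MHE"].iloc[0] == 35.0
        assert table["median_CTRL"].iloc[0] == 3.0


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_example(self):
        q = de.bh_adjust([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(q, [0.04, 0.05, 0.05, 0.05])

    def test_trivial_cases(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(de.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_nan_propagates_excluded_from_m(self):
        q = de.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], de.bh_adjust([0.01, 0.02]))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(de.bh_adjust(p), ref, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_monotonicity(self, pvals, rnd):
        p = np.asarray(pvals)
        q = de.bh_adjust(p)
        assert ((q >= p - 1e-12) | np.isnan(q)).all()
        assert (q[~np.isnan(q)] <= 1).all()
        # permuting inputs permutes outputs identically
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(de.bh_adjust(p[perm]), q[perm], equal_nan=True)
        # monotone: larger p never gets smaller q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def test_significant_features_sorted_by_q():
    table = pd.DataFrame({"fdr": [0.2, 0.01, 0.04, 0.5]},
                         index=["a", "b", "c", "d"])
    assert de.significant_features(table) == ["b", "c"]
    assert de.significant_features(pd.DataFrame({"fdr": [0.5, 0.5]},
                                                index=["a", "b"])) == []
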