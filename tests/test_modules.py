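"""Correlation modules: distances, PAM, silhouette, selection, profiles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from mhelink import cohort as syn
from mhelink import modules as mc
from mhelink.cohort import CohortDesign, generate_serum_panel
from mhelink.matrix import OmicsMatrix

from conftest import make_matrix


def dist_from_points(points):
    """Euclidean distance matrix as a labelled DataFrame."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 1:
        pts = pts.T
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = [f"x{i}" for i in range(len(pts))]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestCorrelationDistance:
    def test_spearman_self_and_antitone(self):
        vals = np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], float)
        corr = mc.spearman_abs_corr(make_matrix(vals, 3, 2))
        assert corr.iloc[0, 0] == 1.0
        assert corr.iloc[0, 1] == pytest.approx(1.0)  # absolute value

    def test_spearman_hand_example(self):
        # x=(1..5), y=(1,3,2,5,4): rho = 1 - 6*4/(5*24) = 0.8
        vals = np.array([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]], float)
        corr = mc.spearman_abs_corr(make_matrix(vals, 3, 2))
        assert corr.iloc[0, 1] == pytest.approx(0.8)

    def test_constant_feature_zeroed_with_warning(self):
        vals = np.array([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7]], float)
        with pytest.warns(UserWarning, match="constant"):
            corr = mc.spearman_abs_corr(make_matrix(vals, 3, 2))
        assert corr.iloc[0, 1] == 0.0
        assert corr.iloc[1, 1] == 1.0

    @pytest.mark.parametrize("r,d", [(1.0, 0.0), (0.0, np.sqrt(2)),
                                     (0.5, np.sqrt(1.5))])
    def test_distance_formula(self, r, d):
        corr = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"],
                            columns=["a", "b"])
        out = mc.corr_distance(corr)
        assert out.iloc[0, 1] == pytest.approx(d)
        assert out.iloc[0, 0] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1))
    def test_distance_bounds(self, r):
        corr = pd.DataFrame([[1.0, r], [r, 1.0]])
        out = mc.corr_distance(corr).to_numpy()
        assert 0 <= out[0, 1] <= np.sqrt(2) + 1e-12
        assert np.allclose(out, out.T)


class TestPAM:
    def test_two_far_pairs(self):
        dist = dist_from_points([0, 1, 10, 11])
        res = mc.pam_cluster(dist, 2)
        labels = res.labels
        assert labels["x0"] == labels["x1"]
        assert labels["x2"] == labels["x3"]
        assert labels["x0"] != labels["x2"]

    def test_matches_exhaustive_medoid_search(self):
        """BUILD+SWAP reaches the global optimum on small instances."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 2))
        dist = dist_from_points(pts)
        D = dist.to_numpy()
        for k in (2, 3):
            res = mc.pam_cluster(dist, k)
            best = min(D[:, list(c)].min(axis=1).sum()
                       for c in itertools.combinations(range(9), k))
            assert res.objective == pytest.approx(best, abs=1e-9)

    def test_k_n_minus_one_pigeonhole(self):
        dist = dist_from_points([0.0, 1.0, 3.0, 6.0, 10.0])
        res = mc.pam_cluster(dist, 4)
        sizes = res.labels.value_counts()
        assert sorted(sizes) == [1, 1, 1, 2]

    def test_invalid_k_rejected(self):
        dist = dist_from_points([0, 1, 2])
        with pytest.raises(ValueError):
            mc.pam_cluster(dist, 3)
        with pytest.raises(ValueError):
            mc.pam_cluster(dist, 1)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(9)
        pts = np.concatenate([rng.normal(0, 0.3, (5, 2)),
                              rng.normal(4, 0.3, (5, 2))])
        dist = dist_from_points(pts)
        res = mc.pam_cluster(dist, 2)
        perm = rng.permutation(len(dist))
        shuffled = dist.iloc[perm, perm]
        res2 = mc.pam_cluster(shuffled, 2)
        joint = pd.concat([res.labels.rename("a"),
                           res2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joint["a"], joint["b"]) == pytest.approx(1.0)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        dist = dist_from_points([0.0, 0.1, 10.0, 10.1])
        labels = pd.Series([1, 1, 2, 2], index=dist.index)
        widths, mean = mc.silhouette_width(dist, labels)
        assert mean == pytest.approx(0.99005, abs=1e-4)

    def test_duplicate_points_full_width(self):
        dist = dist_from_points([0, 0, 5, 5])
        labels = pd.Series([1, 1, 2, 2], index=dist.index)
        widths, mean = mc.silhouette_width(dist, labels)
        assert np.allclose(widths, 1.0)

    def test_single_cluster_rejected(self):
        dist = dist_from_points([0, 1, 2])
        with pytest.raises(ValueError):
            mc.silhouette_width(dist, pd.Series([1, 1, 1], index=dist.index))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_on_small_instances(self, seed):
        """Brute-force/sklearn agreement for n <= 12 without singletons."""
        from sklearn.metrics import silhouette_samples
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        pts = rng.normal(size=(n, 3))
        dist = dist_from_points(pts)
        labels = pd.Series(rng.integers(1, 4, n), index=dist.index)
        while labels.nunique() < 2 or (labels.value_counts() == 1).any():
            labels = pd.Series(rng.integers(1, 4, n), index=dist.index)
        widths, _ = mc.silhouette_width(dist, labels)
        ref = silhouette_samples(dist.to_numpy(), labels.to_numpy(),
                                 metric="precomputed")
        assert np.allclose(widths.to_numpy(), ref, atol=1e-10)

    def test_random_labels_near_zero(self):
        means = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dist = dist_from_points(rng.normal(size=(10, 2)))
            labels = pd.Series(rng.integers(1, 3, 10), index=dist.index)
            if labels.nunique() < 2:
                continue
            means.append(mc.silhouette_width(dist, labels)[1])
        assert abs(np.mean(means)) < 0.1


class TestAltClusterAndSelection:
    def _blob_dist(self, seed=0, centers=(0, 8), per=5):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([rng.normal(c, 0.3, (per, 2)) for c in centers])
        return dist_from_points(pts)

    def test_all_methods_agree_on_separated_blobs(self):
        dist = self._blob_dist()
        ref = mc.pam_cluster(dist, 2).labels
        for method in ("kmeans", "hierarchical"):
            labels = mc.alt_cluster(dist, 2, method).labels
            joint = pd.concat([ref.rename("a"), labels.rename("b")], axis=1)
            assert adjusted_rand_score(joint["a"], joint["b"]) == 1.0

    def test_hierarchical_k_equals_n_singletons(self):
        dist = self._blob_dist(per=3)
        res = mc.alt_cluster(dist, len(dist), "hierarchical")
        assert res.labels.nunique() == len(dist)

    def test_select_modules_two_planted_blocks(self):
        """Correlation data with 2 latent blocks selects k = 2."""
        rng = np.random.default_rng(3)
        n = 40
        u = rng.standard_normal((2, n))
        feats = []
        for block in range(2):
            for _ in range(6):
                feats.append(u[block] * rng.uniform(0.8, 1.2)
                             + rng.standard_normal(n) * 0.3)
        m = make_matrix(np.array(feats), 20, 20)
        dist = mc.corr_distance(mc.spearman_abs_corr(m))
        sel = mc.select_modules(dist, seed=0)
        assert sel.best.k == 2

    def test_pure_noise_flagged_low_signal(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.standard_normal((25, 40)), 20, 20)
        dist = mc.corr_distance(mc.spearman_abs_corr(m))
        with pytest.warns(UserWarning, match="silhouette"):
            sel = mc.select_modules(dist, seed=0)
        assert sel.low_signal
        assert sel.best.mean_silhouette < 0.25

    def test_empty_k_range_rejected(self):
        dist = self._blob_dist(per=3)
        with pytest.raises(ValueError):
            mc.select_modules(dist, k_range=[])

    def test_ari_degrades_as_loadings_shrink(self):
        """Planted-module recovery decays monotonically with signal."""
        aris = []
        for scale in (1.0, 0.25, 0.02):
            mods = syn.default_modules()
            for mod in mods:
                mod.shift = 0.0  # isolate the correlation structure
                for mem in mod.members.values():
                    mem.loading *= scale
                    mem.noise_sd = 0.15
            design = CohortDesign(10, 10, seed=6)
            met, cyt = generate_serum_panel(design, modules=mods,
                                            background_coupling=None)
            members = [f for mod in mods for f in mod.members]
            vals = pd.concat([met.values, cyt.values]).loc[members]
            m = OmicsMatrix(np.log2(vals), design.groups(), "serum")
            dist = mc.corr_distance(mc.spearman_abs_corr(m))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mc.pam_cluster(dist, 6)
            truth = [mod.name for mod in mods for _ in mod.members]
            aris.append(adjusted_rand_score(truth, res.labels.loc[members]))
        assert aris[0] > aris[1] > aris[2]
        assert aris[0] > 0.9


class TestModuleProfiles:
    def test_identical_members(self):
        x = np.array([1.0, 3, 2, 5, 4, 6, 2, 1, 4, 3, 5])
        m = make_matrix(np.vstack([x, x, x]), 6, 5)
        res = mc.pam_cluster(
            mc.corr_distance(mc.spearman_abs_corr(
                make_matrix(np.vstack([x, x, -x]), 6, 5))), 2)
        profiles = mc.module_profiles(m, res)
        p0 = profiles[0]
        z = (x - x.mean()) / x.std(ddof=1)
        member_profile = p0.profile.to_numpy()
        assert np.allclose(np.corrcoef(member_profile, z)[0, 1], 1.0)

    def test_anticorrelated_pair_signs(self):
        x = np.array([1.0, 3, 2, 5, 4, 6, 2, 1, 4, 3, 5])
        m = make_matrix(np.vstack([x, -x]), 6, 5)
        labels = pd.Series([1, 1], index=m.values.index)
        res = mc.ClusteringResult("pam", 1, labels, ["f0"],
                                  pd.Series([0.0, 0.0], index=m.values.index),
                                  0.0)
        profiles = mc.module_profiles(m, res)
        signs = sorted(profiles[0].signs)
        assert signs == [-1, 1]
        corr = np.corrcoef(profiles[0].profile, x)[0, 1]
        assert abs(corr) == pytest.approx(1.0)

    def test_default_cytokine_module_separates_groups(self, default_cohort,
                                                      serum_significant):
        """The cytokine module profile separates MHE from control."""
        dist = mc.corr_distance(mc.spearman_abs_corr(serum_significant))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = mc.select_modules(dist, seed=0, methods=("pam",))
        profiles = mc.module_profiles(serum_significant, sel.best)
        cyto_profile = next(p for p in profiles
                            if "IL-6" in p.members)
        grp = (serum_significant.groups == "MHE").astype(float)
        r = np.corrcoef(cyto_profile.profile, grp)[0, 1]
        assert abs(r) >= 0.6
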