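"""PCA proximity metrics, PLS-DA VIP scores, cross-method robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from msibatch import (
    intergroup_distance,
    intragroup_distance,
    pca_scores,
    plsda_vip,
    qcs_proximity,
    robust_feature_comparison,
)
from msibatch.multivariate import VIPResult

from conftest import make_table


class TestPCA:
    def test_collinear_data_loads_on_first_component(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, -0.5]) + 5
        res = pca_scores(X, n_components=2, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6)) * [3, 2, 1.5, 1, 0.5, 0.2]
        Q = ortho_group.rvs(6, random_state=1)
        r1 = pca_scores(X, n_components=4, scale=False)
        r2 = pca_scores(X @ Q, n_components=4, scale=False)
        np.testing.assert_allclose(
            r1.explained_variance_ratio, r2.explained_variance_ratio, atol=1e-10
        )

    def test_duplicate_observations_share_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 4))
        X[3] = X[0]
        res = pca_scores(X, n_components=2)
        np.testing.assert_allclose(res.scores[3], res.scores[0], atol=1e-10)

    def test_centered_scores_and_monotone_spectrum(self):
        rng = np.random.default_rng(2)
        res = pca_scores(rng.normal(size=(25, 10)), n_components=5)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_component_bound_enforced(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_scores(np.eye(3), n_components=3)

    def test_zero_variance_feature_dropped_when_scaling(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=(10, 3)), np.full(10, 7.0)])
        res = pca_scores(X, n_components=2, scale=True)
        assert res.dropped_features == [3]
        assert len(res.kept_features) == 3


class TestDistances:
    def test_identical_points_zero_distance(self):
        scores = np.zeros((3, 2))
        per, avg = intragroup_distance(scores, ["g"] * 3)
        assert avg == 0.0

    def test_two_point_group(self):
        per, avg = intragroup_distance(np.array([[0, 0], [2, 0]]), ["g", "g"])
        assert per["g"] == pytest.approx(1.0)

    def test_unit_square_matches_geometry_oracle(self):
        corners = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        # oracle: brute-force mean distance to the centroid (0.5, 0.5)
        oracle = np.mean(
            [np.hypot(x - 0.5, y - 0.5) for x, y in corners]
        )
        per, _ = intragroup_distance(corners, ["g"] * 4)
        assert per["g"] == pytest.approx(oracle, abs=1e-10)
        assert per["g"] == pytest.approx(np.sqrt(2) / 2, abs=1e-10)

    def test_345_centroid_distance(self):
        mat, avg = intergroup_distance(
            np.array([[0, 0], [3, 4]]), ["a", "b"]
        )
        assert mat.loc["a", "b"] == pytest.approx(5.0)
        assert avg == pytest.approx(5.0)

    def test_coincident_centroids(self):
        scores = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        mat, avg = intergroup_distance(scores, ["a", "a", "b", "b"])
        assert avg == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_triangle_average(self):
        h = np.sqrt(3)
        pts = np.array([[0, 0], [2, 0], [1, h]])
        _, avg = intergroup_distance(pts, ["a", "b", "c"])
        assert avg == pytest.approx(2.0, abs=1e-10)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(12, 2))
        labels = np.array(["a", "b", "c"] * 4)
        perm = rng.permutation(12)
        _, avg1 = intragroup_distance(scores, labels)
        _, avg2 = intragroup_distance(scores[perm], labels[perm])
        assert avg1 == pytest.approx(avg2)

    def test_single_group_intergroup_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            intergroup_distance(np.zeros((3, 2)), ["a"] * 3)

    def test_single_score_column_rejected(self):
        with pytest.raises(ValueError, match="2 score columns"):
            intragroup_distance(np.zeros((3, 1)), ["a"] * 3)


class TestQCSProximity:
    def _mixed_table(self, qcs_jitter, seed=0):
        rng = np.random.default_rng(seed)
        n_qcs, n_tis, p = 12, 12, 8
        qcs = 10 + qcs_jitter * rng.normal(size=(n_qcs, p))
        tis = 10 + rng.lognormal(0, 0.5, size=(n_tis, p))
        X = np.abs(np.vstack([qcs, tis]))
        return make_table(
            X,
            [f"S{i % 6 + 1}" for i in range(24)],
            ["day1"] * 24,
            ["qcs"] * n_qcs + ["tissue"] * n_tis,
            groups=[""] * n_qcs + ["g1", "g2"] * (n_tis // 2),
        )

    def test_identical_qcs_spots_have_zero_distance(self):
        t = self._mixed_table(qcs_jitter=0.0)
        assert qcs_proximity(t) == pytest.approx(0.0, abs=1e-8)

    def test_larger_slide_effects_give_larger_distance(self, default_table, default_truth):
        # removing the known multiplicative slide effects analytically
        # must strictly shrink QCS proximity
        t = default_table
        factors = np.array(
            [
                np.exp(
                    default_truth.slide_effects[s]
                    + float(default_truth.outlier_offsets.get(s, 0.0))
                )
                for s in t.obs_meta["slide_id"]
            ]
        )
        cleaned = t.with_intensities(t.intensities / factors[:, None])
        assert qcs_proximity(cleaned) < qcs_proximity(t)

    def test_requires_qcs_observations(self, default_table):
        with pytest.raises(ValueError, match="QCS"):
            qcs_proximity(default_table.tissue_only())


class TestVIP:
    def _groups(self, n_per=10, p=50, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3 * n_per, p))
        labels = np.repeat(["g1", "g2", "g3"], n_per)
        X[labels == "g1", 0] += shift  # feature 0 separates g1
        return X, labels

    def test_mean_squared_vip_is_one(self):
        X, labels = self._groups(shift=2.0)
        res = plsda_vip(X, labels)
        assert (res.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_informative_feature_tops_ranking(self):
        # 3-sigma group shift on one of 50 features, 20 seeds: always found
        for seed in range(20):
            X, labels = self._groups(shift=3.0, seed=seed)
            res = plsda_vip(X, labels)
            assert res.vip.idxmax() == 0
            assert res.vip.iloc[0] > 1.2

    def test_permuted_labels_rarely_select_the_feature(self):
        X, labels = self._groups(shift=3.0, seed=1)
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(50):
            res = plsda_vip(X, rng.permutation(labels))
            hits += res.vip.iloc[0] > 1.2
        assert hits <= 10  # <= 20% of permutations

    def test_component_rank_bound(self):
        X, labels = self._groups()
        with pytest.raises(ValueError, match="rank"):
            plsda_vip(X, labels, n_components=200)

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="< 2"):
            plsda_vip(X, ["a", "a", "a", "a", "b"])


class TestRobustComparison:
    def _vip(self, values, threshold=1.2):
        s = pd.Series(values, index=[f"f{i}" for i in range(len(values))])
        return VIPResult(
            vip=s, n_components=2, threshold=threshold,
            selected=list(s.index[s > threshold]),
        )

    def test_identical_vips_make_every_selection_robust(self):
        v = self._vip([2.0, 0.5, 1.5])
        grid = robust_feature_comparison({"raw": v, "Combat": v})
        assert grid["robust"].tolist() == [True, False, True]

    def test_raw_only_feature_lands_in_dropped_set(self):
        raw = self._vip([2.0, 0.5])
        corr = self._vip([0.4, 0.5])
        grid = robust_feature_comparison({"raw": raw, "Combat": corr})
        assert grid.loc["f0", "dropped"]
        assert not grid.loc["f1", "dropped"]

    def test_mismatched_features_rejected(self):
        a = self._vip([1.0, 2.0])
        b = VIPResult(
            vip=pd.Series([1.0], index=["x"]), n_components=1,
            threshold=1.2, selected=[],
        )
        with pytest.raises(ValueError, match="mismatched"):
            robust_feature_comparison({"raw": a, "m": b})

    def test_drifting_markers_selected_only_after_correction(self, default_table, default_truth):
        """Group markers hidden by strong acquisition drift become
        distinctive once the drift is removed analytically."""
        t = default_table
        # amplify drift on the marker features so it masks the group signal
        drift = np.zeros(t.n_feat)
        marker_ids = sorted({f for ids in default_truth.group_markers.values() for f in ids})
        idx = [t.feature_index(f) for f in marker_ids]
        order = t.obs_meta["measurement_order"].to_numpy()
        X = t.intensities.copy()
        X[:, idx] *= np.exp(-0.02 * order)[:, None]
        masked = t.with_intensities(X)
        corrected = masked.with_intensities(t.intensities)  # drift removed exactly

        vip_masked = plsda_vip(masked.tissue_only())
        vip_corr = plsda_vip(corrected.tissue_only())
        n_masked = sum(f in vip_masked.selected for f in marker_ids)
        n_corr = sum(f in vip_corr.selected for f in marker_ids)
        assert n_corr > n_masked
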