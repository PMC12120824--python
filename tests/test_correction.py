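"""Batch correction: MODWT primitive, ComBat, WaveICA, method grid."""

import shutil
import subprocess

import numpy as np
import pytest

from msibatch import (
    CombatCorrector,
    WaveICACorrector,
    apply_corrections,
    combat_correct,
    cv_percent,
    generate_batch_experiment,
    waveica_correct,
)
from msibatch._modwt import imodwt, max_level, modwt

from conftest import make_table


class TestMODWT:
    @pytest.mark.parametrize("n", [8, 13, 72, 100])
    @pytest.mark.parametrize("wavelet", ["haar", "db4", "sym4"])
    def test_round_trip_any_length(self, n, wavelet):
        rng = np.random.default_rng(n)
        x = rng.normal(size=(n, 3))
        details, smooth = modwt(x, wavelet)
        np.testing.assert_allclose(imodwt(details, smooth, wavelet), x, atol=1e-9)

    def test_energy_conservation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(64, 5))
        details, smooth = modwt(x, "db2")
        energy = sum((d**2).sum() for d in details) + (smooth**2).sum()
        assert energy == pytest.approx((x**2).sum(), rel=1e-10)

    def test_default_depth(self):
        assert max_level(180) == 7
        assert max_level(13) == 3

    def test_shift_equivariance(self):
        # MODWT with circular boundary commutes with circular shifts
        rng = np.random.default_rng(2)
        x = rng.normal(size=24)
        d1, s1 = modwt(x, "haar", 3)
        d2, s2 = modwt(np.roll(x, 5), "haar", 3)
        for a, b in zip(d1, d2):
            np.testing.assert_allclose(np.roll(a, 5), b, atol=1e-10)
        np.testing.assert_allclose(np.roll(s1, 5), s2, atol=1e-10)


def two_batch_data(n_per, p, delta=0.0, scale2=1.0, seed=0):
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1, p)
    x1 = mu + rng.normal(0, 1, (n_per, p))
    x2 = mu + delta + rng.normal(0, scale2, (n_per, p))
    X = np.vstack([x1, x2])
    batch = np.array(["b1"] * n_per + ["b2"] * n_per)
    return X, batch


class TestCombat:
    def test_single_batch_identity(self):
        X, _ = two_batch_data(20, 10)
        out = CombatCorrector().fit_transform(X, np.array(["b1"] * 40))
        np.testing.assert_allclose(out, X, atol=1e-8)

    def test_additive_offset_removed_at_large_n(self):
        delta = 3.0
        X, batch = two_batch_data(200, 30, delta=delta, seed=1)
        out = CombatCorrector().fit_transform(X, batch)
        gap = np.abs(out[batch == "b2"].mean(axis=0) - out[batch == "b1"].mean(axis=0))
        assert gap.max() < 0.05 * delta

    def test_variance_ratio_equalized(self):
        X, batch = two_batch_data(200, 30, scale2=2.0, seed=2)
        out = CombatCorrector().fit_transform(X, batch)
        v1 = out[batch == "b1"].var(axis=0, ddof=1)
        v2 = out[batch == "b2"].var(axis=0, ddof=1)
        ratio = v2 / v1
        assert np.median(ratio) == pytest.approx(1.0, abs=0.2)

    def test_grand_mean_preserved_on_balanced_design(self):
        X, batch = two_batch_data(50, 20, delta=1.5, seed=3)
        out = CombatCorrector().fit_transform(X, batch)
        before = X.mean(axis=0)
        after = out.mean(axis=0)
        span = X.std(axis=0)
        assert (np.abs(after - before) / span).max() < 0.01

    def test_eb_shrinkage_limits(self):
        # tau^2 -> inf: gamma* -> gamma_hat; tau^2 -> 0: gamma* -> gamma_bar
        X, batch = two_batch_data(30, 25, delta=1.0, seed=4)
        model = CombatCorrector().fit(X, batch)
        g_hat, g_bar = model.gamma_hat_, model.gamma_bar_
        d_sq, n_i = model.delta_sq_star_, model.batch_sizes_
        for i in range(2):
            for tau2, target in [(1e9, g_hat[i]), (1e-12, np.full_like(g_hat[i], g_bar[i]))]:
                g_star = (n_i[i] * tau2 * g_hat[i] + d_sq[i] * g_bar[i]) / (
                    n_i[i] * tau2 + d_sq[i]
                )
                np.testing.assert_allclose(g_star, target, atol=1e-3)

    def test_singleton_batch_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="single observation"):
            CombatCorrector().fit(X, np.array(["a"] * 4 + ["b"]))

    def test_zero_variance_feature_skipped_with_log(self):
        X, batch = two_batch_data(10, 5, delta=1.0, seed=5)
        table = make_table(
            np.exp(np.column_stack([X, np.zeros(len(X))])),
            [f"S{i}" for i in range(len(X))],
            batch,
            ["qcs"] * len(X),
        )
        res = combat_correct(table, batch_key="day")
        assert len(res.model.skipped_features_) == 1
        assert any("zero-variance" in line for line in res.log)
        np.testing.assert_allclose(
            res.table.intensities[:, -1], table.intensities[:, -1]
        )

    def test_matches_bioconductor_sva(self, tmp_path):
        """Independent oracle: sva::ComBat on the same fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; the cross-check cannot run")
        X, batch = two_batch_data(10, 15, delta=1.0, scale2=1.5, seed=6)
        ours = CombatCorrector().fit_transform(X, batch)
        np.savetxt(tmp_path / "X.csv", X.T, delimiter=",")
        (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
        script = f"""
        suppressMessages(library(sva))
        X <- as.matrix(read.csv('{tmp_path}/X.csv', header=FALSE))
        batch <- readLines('{tmp_path}/batch.txt')
        Y <- ComBat(dat=X, batch=batch, par.prior=TRUE)
        write.table(Y, '{tmp_path}/Y.csv', sep=',', row.names=FALSE, col.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = np.loadtxt(tmp_path / "Y.csv", delimiter=",").T
        # the two EB solvers stop on different criteria (absolute vs
        # relative 1e-4 change), so agreement is to ~1e-4, not roundoff
        np.testing.assert_allclose(ours, theirs, atol=1e-3)


class TestWaveICA:
    def _drifted_table(self, seed=0):
        return generate_batch_experiment(seed=seed)[0]

    def test_threshold_above_one_reconstructs_input(self):
        t = self._drifted_table()
        res = waveica_correct(t, t_threshold=1.01)
        assert res.model.removed_ == []
        np.testing.assert_allclose(
            res.table.intensities, t.intensities, rtol=1e-8, atol=1e-8
        )

    def test_step_change_aligned_with_batch_removed(self):
        rng = np.random.default_rng(3)
        n, p = 48, 20
        X = rng.normal(0, 0.2, (n, p))
        X[n // 2 :] += 2.0  # step at the batch boundary, all features
        batch = np.array(["d1"] * (n // 2) + ["d2"] * (n // 2))

        def feature_r2(M):
            r2 = []
            for j in range(p):
                col = M[:, j]
                m1, m2 = col[: n // 2].mean(), col[n // 2 :].mean()
                between = (n // 2) * ((m1 - col.mean()) ** 2 + (m2 - col.mean()) ** 2)
                total = ((col - col.mean()) ** 2).sum()
                r2.append(between / total)
            return np.array(r2)

        assert feature_r2(X).min() > 0.5
        model = WaveICACorrector(t_threshold=0.05, random_state=0)
        out = model.fit_transform(X, batch)
        assert feature_r2(out).max() < 0.1

    def test_non_power_of_two_length(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(13, 6))
        batch = np.array(["a"] * 6 + ["b"] * 7)
        model = WaveICACorrector(t_threshold=1.01)
        out = model.fit_transform(X, batch)
        np.testing.assert_allclose(out, X, atol=1e-8)

    def test_non_unique_order_rejected(self, default_table):
        t = default_table.copy()
        t.obs_meta.loc[1, "measurement_order"] = t.obs_meta.loc[0, "measurement_order"]
        with pytest.raises(ValueError, match="unique"):
            waveica_correct(t)

    def test_bad_component_count_rejected(self):
        X = np.random.default_rng(5).normal(size=(16, 4))
        with pytest.raises(ValueError, match="component"):
            WaveICACorrector(n_components=0).fit(X, np.array(["a", "b"] * 8))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shrinks_day_level_spread_of_the_analyte(self, seed):
        t = self._drifted_table(seed=seed)

        def day_spread(table):
            q = table.qcs_only()
            logs = np.log(q.feature_values("propranolol"))
            days = q.obs_meta["day"].to_numpy()
            return np.std([logs[days == d].mean() for d in np.unique(days)])

        res = waveica_correct(t)
        assert day_spread(res.table) < day_spread(t)


class TestMethodGrid:
    def test_labels_follow_the_printed_convention(self, default_table):
        results = apply_corrections(
            default_table,
            ["combat", "tic+combat"],
            analyte_feat="propranolol",
            is_feat="propranolol_d7",
        )
        assert [r.method for r in results] == ["Combat", "TIC + Combat"]

    def test_empty_spec_gives_empty_list(self, default_table):
        assert apply_corrections(default_table, []) == []

    def test_full_grid_labels(self, default_table):
        specs = ["raw", "tic", "is", "tic+combat", "tic+waveica", "combat", "waveica"]
        results = apply_corrections(
            default_table, specs,
            analyte_feat="propranolol", is_feat="propranolol_d7",
        )
        assert [r.method for r in results] == [
            "raw", "TIC", "IS", "TIC + Combat", "TIC + WaveICA", "Combat", "WaveICA",
        ]
        for r in results:
            assert r.table.n_obs == default_table.n_obs
            assert r.table.feat_ids == default_table.feat_ids

    def test_unknown_method_lists_registry(self, default_table):
        with pytest.raises(ValueError, match="registered"):
            apply_corrections(default_table, ["normae"])
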