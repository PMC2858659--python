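"""GLM engine: HRF, design, AR(1) fit, contrasts, thresholds, clusters."""

import numpy as np
import pytest
from scipy import ndimage, stats

from wmfusion import fusion_glm, paradigm_sim
from wmfusion.fusion_glm import (
    DesignMatrix,
    HRFParams,
    StatMap,
    ThresholdSpec,
    build_design_matrix,
    canonical_hrf,
    cluster_extent_mc,
    contrast_map,
    dct_drift_basis,
    fit_glm_ar1,
    group_onesample,
    label_clusters,
    threshold_fdr,
    threshold_fwe,
)
from wmfusion.spectral import BandPowerTable


@pytest.fixture
def tiny_design(tiny_config, rng):
    schedule = paradigm_sim.make_trial_schedule(tiny_config, rng)
    truth = paradigm_sim.default_truth(tiny_config)
    tp = paradigm_sim.draw_band_power(schedule, truth, rng)
    dm = build_design_matrix(
        schedule, tp.as_band_power_table(), tiny_config.tr_s, tiny_config.n_scans
    )
    return schedule, tp, dm


class TestHRF:
    def test_zero_at_onset_and_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_peaks_near_five_seconds(self):
        dt = 0.01
        h = canonical_hrf(dt)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=2 * dt)

    def test_undershoot_present(self):
        h = canonical_hrf(0.1)
        assert h.min() < 0

    def test_length_covers_params(self):
        p = HRFParams(length_s=40.0)
        h = canonical_hrf(0.5, p)
        assert len(h) == pytest.approx(40.0 / 0.5 + 1, abs=1)


class TestDesignMatrix:
    def test_nine_regressors_per_load(self, tiny_design):
        _, _, dm = tiny_design
        ss2 = [n for n in dm.names if n.startswith("ss2")]
        ss5 = [n for n in dm.names if n.startswith("ss5")]
        assert len(ss2) == 9 and len(ss5) == 9
        assert sum(1 for n in ss2 if "_mod_" in n) == 6

    def test_drift_column_count_matches_formula(self):
        n_scans, tr, cutoff = 554, 1.815, 128.0
        drift = dct_drift_basis(n_scans, tr, cutoff)
        assert drift.shape[1] == int(np.floor(2 * n_scans * tr / cutoff)) == 15
        # independent period enumeration: DCT component k has period
        # 2*N*TR/k, which must stay >= the cutoff
        periods = [2 * n_scans * tr / k for k in range(1, drift.shape[1] + 1)]
        assert all(p >= cutoff for p in periods)
        assert 2 * n_scans * tr / (drift.shape[1] + 1) < cutoff

    def test_drift_columns_orthogonal(self):
        drift = dct_drift_basis(300, 2.0, 100.0)
        gram = drift.T @ drift
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-10)

    def test_constant_modulator_dropped_with_warning(self, tiny_config, rng):
        schedule = paradigm_sim.make_trial_schedule(tiny_config, rng)
        truth = paradigm_sim.default_truth(tiny_config)
        tp = paradigm_sim.draw_band_power(schedule, truth, rng)
        table = tp.as_band_power_table()
        j = list(table.bands).index("theta")
        table.rms[:, j] = 5.0  # constant within each load
        with pytest.warns(UserWarning, match="constant"):
            dm = build_design_matrix(
                schedule, table, tiny_config.tr_s, tiny_config.n_scans
            )
        assert "ss2_mod_theta" in dm.dropped
        assert "ss2_mod_theta" not in dm.names
        assert not np.any(np.all(dm.X == 0, axis=0))

    def test_modulator_columns_mean_centered_per_load(self, tiny_design):
        # a modulator column sums to ~0 against the retention boxcar's span
        _, tp, dm = tiny_design
        col = dm.column("ss2_mod_alpha1")
        assert abs(col.sum()) < np.abs(col).sum() * 0.2

    def test_trial_count_mismatch_rejected(self, tiny_config, rng):
        schedule = paradigm_sim.make_trial_schedule(tiny_config, rng)
        bad = BandPowerTable(
            trial_index=np.arange(3),
            loads=np.array(["ss2", "ss5", "ss2"]),
            bands=("theta",),
            rms=np.ones((3, 1)),
        )
        with pytest.raises(ValueError, match="retention events"):
            build_design_matrix(schedule, bad, tiny_config.tr_s, tiny_config.n_scans)


class TestFit:
    def test_noiseless_recovery(self, tiny_design, rng):
        _, _, dm = tiny_design
        beta = rng.standard_normal((dm.X.shape[1], 7))
        Y = dm.X @ beta
        fit = fit_glm_ar1(Y, dm)
        np.testing.assert_allclose(fit.betas, beta, atol=1e-8)
        assert np.all(fit.sigma2 < 1e-16)
        assert fit.df == dm.n_scans - dm.X.shape[1]

    def test_white_noise_rho_near_zero(self, tiny_design, rng):
        _, _, dm = tiny_design
        Y = rng.standard_normal((dm.n_scans, 500))
        fit = fit_glm_ar1(Y, dm)
        assert -0.05 <= fit.rho_hat <= 0.05

    def test_ar1_rho_recovered(self, desk_config, rng):
        schedule = paradigm_sim.make_trial_schedule(desk_config, rng)
        truth = paradigm_sim.default_truth(desk_config)
        tp = paradigm_sim.draw_band_power(schedule, truth, rng)
        dm = build_design_matrix(
            schedule, tp.as_band_power_table(), desk_config.tr_s, desk_config.n_scans
        )
        from wmfusion.paradigm_sim import _ar1_noise

        Y = _ar1_noise(rng, dm.n_scans, 500, rho=0.4, sd=1.0)
        fit = fit_glm_ar1(Y, dm)
        assert 0.3 <= fit.rho_hat <= 0.5

    def test_forced_zero_rho_equals_ols(self, tiny_design, rng):
        _, _, dm = tiny_design
        Y = rng.standard_normal((dm.n_scans, 50))
        fit = fit_glm_ar1(Y, dm, rho=0.0)
        ols = np.linalg.pinv(dm.X) @ Y
        np.testing.assert_allclose(fit.betas, ols, atol=1e-10)
        assert fit.rho_hat == 0.0

    def test_rank_deficient_design_named(self, tiny_design, rng):
        _, _, dm = tiny_design
        X = np.column_stack([dm.X, dm.X[:, 0]])
        bad = DesignMatrix(
            X=X, names=dm.names + ["dup"], tr_s=dm.tr_s, microtime_bins=16
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm_ar1(rng.standard_normal((dm.n_scans, 3)), bad)


class TestContrast:
    def test_scale_invariance(self, tiny_design, rng):
        _, _, dm = tiny_design
        Y = rng.standard_normal((dm.n_scans, 40))
        c = {"ss2_retention": 1.0}
        t1 = contrast_map(fit_glm_ar1(Y, dm, rho=0.0), c).t
        t2 = contrast_map(fit_glm_ar1(10.0 * Y, dm, rho=0.0), c).t
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_column_rescale_with_rescaled_contrast(self, tiny_design, rng):
        _, _, dm = tiny_design
        Y = rng.standard_normal((dm.n_scans, 20))
        j = dm.names.index("ss5_retention")
        X2 = dm.X.copy()
        X2[:, j] *= 4.0
        dm2 = DesignMatrix(X=X2, names=list(dm.names), tr_s=dm.tr_s, microtime_bins=16)
        c1 = np.zeros(len(dm.names)); c1[j] = 1.0
        c2 = np.zeros(len(dm.names)); c2[j] = 1.0 / 4.0
        t1 = contrast_map(fit_glm_ar1(Y, dm, rho=0.0), c1).t
        t2 = contrast_map(fit_glm_ar1(Y, dm2, rho=0.0), c2).t
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_two_regressor_toy_matches_hand_formula(self):
        # intercept + box on a printed 6-scan series, solved by explicit
        # 2x2 normal equations
        box = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        y = np.array([10.0, 12.0, 13.0, 9.0, 14.0, 11.0])
        X = np.column_stack([np.ones(6), box])
        xtx = X.T @ X
        beta = np.linalg.solve(xtx, X.T @ y)
        resid = y - X @ beta
        df = 6 - 2
        sigma2 = resid @ resid / df
        c = np.array([0.0, 1.0])
        t_expect = (c @ beta) / np.sqrt(sigma2 * c @ np.linalg.inv(xtx) @ c)
        dm = DesignMatrix(X=X, names=["intercept", "box"], tr_s=1.0, microtime_bins=1)
        fit = fit_glm_ar1(y[:, None], dm, rho=0.0)
        tm = contrast_map(fit, {"box": 1.0})
        assert tm.t[0] == pytest.approx(t_expect, rel=1e-9)
        assert tm.df == df

    def test_null_modulator_exceeds_3p1_at_nominal_rate(self, tiny_design, rng):
        _, _, dm = tiny_design
        Y = rng.standard_normal((dm.n_scans, 20000))
        fit = fit_glm_ar1(Y, dm, rho=0.0)
        tm = contrast_map(fit, {"ss2_mod_gamma": 1.0})
        frac = np.mean(tm.t > 3.1)
        # one-tailed p(t_df > 3.1) with df ~ 90 here is ~0.0013
        nominal = stats.t.sf(3.1, df=fit.df)
        assert frac == pytest.approx(nominal, abs=3 * np.sqrt(nominal / 20000))

    def test_zero_contrast_rejected(self, tiny_design, rng):
        _, _, dm = tiny_design
        fit = fit_glm_ar1(rng.standard_normal((dm.n_scans, 2)), dm, rho=0.0)
        with pytest.raises(ValueError):
            contrast_map(fit, np.zeros(len(dm.names)))


class TestGroup:
    def test_sixteen_subjects_df_15(self, rng):
        maps = [rng.standard_normal((4, 4, 2)) for _ in range(16)]
        gm = group_onesample(maps)
        assert gm.df == 15

    def test_textbook_t(self):
        maps = [np.full((2, 2, 1), v) for v in (1.0, 2.0, 3.0, 4.0)]
        gm = group_onesample(maps)
        assert gm.t[0, 0, 0] == pytest.approx(3.872983, rel=1e-5)

    def test_zero_variance_sentinel_no_crash(self):
        maps = [np.ones((2, 2, 1)) for _ in range(5)]
        gm = group_onesample(maps)
        assert np.all(np.isinf(gm.t))

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            group_onesample([np.zeros((2, 2, 2)), np.zeros((3, 2, 2))])


class TestThresholds:
    def make_map(self, t, df=15):
        return StatMap(t=np.asarray(t, dtype=float), df=df)

    def test_bonferroni_divides_alpha(self, rng):
        df = 30
        t = stats.t.isf(0.05 / 1000, df=df) + 0.01  # just past the corrected bar
        m = self.make_map(np.full((10, 10, 10), 0.0), df=df)
        m.t[0, 0, 0] = t
        mask = threshold_fwe(m, alpha=0.05)
        assert mask.sum() == 1 and mask[0, 0, 0]

    def test_single_voxel_reduces_to_alpha(self):
        df = 20
        m = self.make_map([[[stats.t.isf(0.04, df=df)]]], df=df)
        assert threshold_fwe(m, alpha=0.05).all()
        m2 = self.make_map([[[stats.t.isf(0.06, df=df)]]], df=df)
        assert not threshold_fwe(m2, alpha=0.05).any()

    def test_bonferroni_controls_fwe_under_null(self, rng):
        df = 40
        hits = 0
        n_runs = 400
        for _ in range(n_runs):
            t = stats.t.rvs(df=df, size=(500,), random_state=rng)
            m = self.make_map(t.reshape(5, 10, 10), df=df)
            hits += threshold_fwe(m, alpha=0.05).any()
        assert hits / n_runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_fdr_bh_three_rejections_example(self):
        df = 10
        pvals = np.array([0.001, 0.02, 0.03, 0.2])
        t = stats.t.isf(pvals, df=df)
        m = self.make_map(t.reshape(4, 1, 1), df=df)
        assert threshold_fdr(m, q=0.05).sum() == 3

    def test_fdr_monotone_in_q(self, rng):
        t = stats.t.rvs(df=15, size=(6, 6, 6), random_state=rng) + 0.8
        m = self.make_map(t)
        counts = [threshold_fdr(m, q=q).sum() for q in (0.01, 0.05, 0.1, 0.3)]
        assert counts == sorted(counts)

    def test_threshold_spec_validation(self):
        assert ThresholdSpec().validate() == []
        assert any("voxel_p" in v for v in ThresholdSpec(voxel_p=1.5).validate())
        assert any("k_voxels" in v for v in ThresholdSpec(k_voxels=0).validate())


class TestClusters:
    def test_two_isolated_voxels(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        table = label_clusters(mask)
        assert len(table) == 2
        assert set(table["size"]) == {1}

    def test_edge_neighbours_connectivity(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = mask[2, 2, 1] = True  # share an edge (diagonal in-plane)
        assert len(label_clusters(mask, connectivity=18)) == 1
        assert len(label_clusters(mask, connectivity=6)) == 2

    def test_corner_neighbours_need_26(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True  # share only a corner
        assert len(label_clusters(mask, connectivity=18)) == 2
        assert len(label_clusters(mask, connectivity=26)) == 1

    def test_empty_mask(self):
        assert label_clusters(np.zeros((4, 4, 4), dtype=bool)).empty

    def test_peak_statistic_reported(self):
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[1:3, 1:3, 0] = True
        t = np.zeros((4, 4, 1))
        t[2, 2, 0] = -7.0
        table = label_clusters(mask, t=t)
        assert table["peak_t"].iloc[0] == -7.0
        assert table["peak_index"].iloc[0] == (2, 2, 0)


class TestClusterExtentMC:
    def test_unsmoothed_matches_bernoulli_oracle(self):
        # with no smoothing the procedure reduces to independent voxels at
        # the threshold probability; brute-force Bernoulli enumeration is
        # the oracle
        grid = (10, 10, 10)
        p = 0.01
        rng = np.random.default_rng(21)
        structure = ndimage.generate_binary_structure(3, 2)
        maxs = np.empty(10_000, dtype=int)
        for i in range(10_000):
            mask = rng.random(grid) < p
            labels, n = ndimage.label(mask, structure=structure)
            maxs[i] = np.bincount(labels.ravel())[1:].max() if n else 0
        k_oracle = 1
        while np.mean(maxs >= k_oracle) >= 0.01:
            k_oracle += 1
        k = cluster_extent_mc(
            grid, (3.0, 3.0, 3.0), 0.0, p, 0.01,
            n_iter=10_000, rng=np.random.default_rng(22),
        )
        assert abs(k - k_oracle) <= 1

    def test_stricter_voxel_p_never_larger_k(self):
        ks = [
            cluster_extent_mc(
                (12, 12, 12), (3.0, 3.0, 3.0), 6.0, vp, 0.05,
                n_iter=300, rng=np.random.default_rng(5),
            )
            for vp in (0.0001, 0.001, 0.01)
        ]
        assert ks == sorted(ks)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            cluster_extent_mc((5, 5, 5), 3.0, 9.0, 0.6, 0.01, n_iter=200)
        with pytest.raises(ValueError):
            cluster_extent_mc((5, 5, 5), 3.0, 9.0, 0.001, 0.01, n_iter=50)
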