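"""HRF kernel, design assembly, detrending and voxelwise GLM fitting."""

import numpy as np
import pytest
from scipy import stats

from fatiguemap import (
    BoldDataset,
    ConfigurationError,
    DesignMatrix,
    HRFParams,
    ValidationError,
    build_design_matrix,
    contrast_t,
    detrend_timeseries,
    fit_glm,
    gamma_hrf,
    group_difference_map,
    interpolate_amplitudes,
)
from fatiguemap.glm import StatMap, ols_fit, _gamma_kernel
from fatiguemap.paradigm import RATING_SCALES

from conftest import constant_ratings, single_event_schedule


def make_amplitudes(schedule, fatigue_values=None):
    amps = {}
    for s in RATING_SCALES:
        ratings = constant_ratings(50.0, scale=s, n_boundaries=schedule.n_runs + 1)
        amps[s] = interpolate_amplitudes(schedule, ratings)
    if fatigue_values is not None:
        amps["fatigue"].amplitudes[:] = fatigue_values
    return amps


def bold_from_array(arr, mask=None, run_boundaries=(0,), tr=2.0):
    arr = np.asarray(arr, dtype=float)
    if mask is None:
        mask = np.ones(arr.shape[:3], dtype=bool)
    return BoldDataset(data=arr, tr_s=tr, brain_mask=mask,
                       run_boundaries=run_boundaries)


class TestGammaHRF:
    def test_peak_at_shape_times_scale(self):
        p = HRFParams(shape=8.6, scale_s=0.547, dt_s=0.001)
        t, h = gamma_hrf(p)
        assert t[np.argmax(h)] == pytest.approx(8.6 * 0.547, abs=0.002)

    def test_zero_at_origin_unit_at_peak_nonnegative(self):
        t, h = gamma_hrf(HRFParams())
        assert h[0] == 0.0
        assert h.max() == 1.0
        assert (h >= 0).all()

    def test_closed_form_matches_kernel(self):
        # independent scalar evaluation of ((t/(p q))^p) e^(p - t/q)
        import math

        p, q, tval = 8.6, 0.547, 3.0
        expected = (tval / (p * q)) ** p * math.exp(p - tval / q)
        assert _gamma_kernel(np.array([tval]), p, q)[0] == pytest.approx(expected)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            HRFParams(shape=-1)
        with pytest.raises(ConfigurationError):
            HRFParams(dt_s=0)
        with pytest.raises(ConfigurationError):
            HRFParams(duration_s=1.0)  # peak at 4.7 s not covered


class TestBuildDesignMatrix:
    def test_single_impulse_unit_column_is_sampled_hrf(self):
        sched = single_event_schedule(onset_s=0.0)
        amps = make_amplitudes(sched)
        hrf = HRFParams()
        dm = build_design_matrix(sched, amps, hrf=hrf, tr_s=2.0,
                                 n_volumes_per_run=15, n_discard=0)
        t, h = gamma_hrf(hrf)
        vol_times = np.arange(15) * 2.0
        expected = np.interp(vol_times, t, h, right=0.0)
        assert np.allclose(dm.column("unit"), expected, atol=1e-12)

    def test_zero_amplitudes_give_zero_column(self, small_schedule):
        amps = make_amplitudes(small_schedule, fatigue_values=0.0)
        dm = build_design_matrix(small_schedule, amps, tr_s=2.0,
                                 n_volumes_per_run=20, n_discard=0)
        assert np.all(dm.column("amr_fatigue") == 0.0)

    def test_superposition_of_two_trials(self):
        """AMR column equals a1*h(t-t1) + a2*h(t-t2) (direct-sum oracle)."""
        from fatiguemap.paradigm import generate_schedule

        sched = generate_schedule(1, 2, seed=3)
        a1, a2 = 0.3, 0.8
        amps = make_amplitudes(sched)
        for s in RATING_SCALES:
            amps[s].amplitudes[:] = (a1, a2)
        hrf = HRFParams()
        dm = build_design_matrix(sched, amps, hrf=hrf, tr_s=2.0,
                                 n_volumes_per_run=20, n_discard=0)
        t, h = gamma_hrf(hrf)
        vol_times = np.arange(20) * 2.0
        oracle = a1 * np.interp(vol_times, t + 0.0, h, left=0.0, right=0.0) + \
            a2 * np.interp(vol_times, t + 8.0, h, left=0.0, right=0.0)
        assert np.allclose(dm.column("amr_fatigue"), oracle, atol=1e-9)

    def test_linear_in_amplitudes(self, small_schedule, rng):
        base = rng.uniform(0, 1, small_schedule.n_trials)
        dm1 = build_design_matrix(
            small_schedule, make_amplitudes(small_schedule, base),
            tr_s=2.0, n_volumes_per_run=20, n_discard=0)
        dm3 = build_design_matrix(
            small_schedule, make_amplitudes(small_schedule, 3.0 * base),
            tr_s=2.0, n_volumes_per_run=20, n_discard=0)
        assert np.allclose(dm3.column("amr_fatigue"),
                           3.0 * dm1.column("amr_fatigue"), atol=1e-12)

    def test_discarded_volumes_shrink_rows(self, small_schedule):
        amps = make_amplitudes(small_schedule)
        dm = build_design_matrix(small_schedule, amps, tr_s=2.0,
                                 n_volumes_per_run=20, n_discard=5)
        assert dm.n_volumes == 2 * 15
        assert dm.run_boundaries == (0, 15)

    def test_detrend_adds_per_run_drift_columns(self, small_schedule):
        amps = make_amplitudes(small_schedule)
        dm = build_design_matrix(small_schedule, amps, tr_s=2.0,
                                 n_volumes_per_run=20, n_discard=0, detrend=True)
        assert "drift_run1_lin" in dm.column_labels
        assert dm.n_regressors == 7 + 4

    def test_length_mismatch_rejected(self, small_schedule, schedule_6x32):
        amps = make_amplitudes(schedule_6x32)
        with pytest.raises(ValidationError, match="events"):
            build_design_matrix(small_schedule, amps)


class TestDetrend:
    def test_exactly_linear_series_becomes_zero(self):
        t = np.arange(20, dtype=float)
        arr = np.tile(3.0 + 0.5 * t, (2, 2, 2, 1))
        out = detrend_timeseries(bold_from_array(arr))
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_line_plus_sinusoid_leaves_projected_sinusoid(self):
        """Closed-form projection oracle for a line + sinusoid input."""
        n = 40
        t = np.arange(n, dtype=float)
        sin = np.sin(2 * np.pi * t / 7.0)
        series = 5.0 - 0.3 * t + sin
        X = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        oracle = sin - X @ np.linalg.lstsq(X, sin, rcond=None)[0]
        arr = series.reshape(1, 1, 1, n)
        out = detrend_timeseries(bold_from_array(arr))
        assert np.allclose(out.data[0, 0, 0], oracle, atol=1e-10)

    def test_projection_shrinks_variance(self, rng):
        arr = rng.standard_normal((3, 3, 3, 30))
        out = detrend_timeseries(bold_from_array(arr))
        assert np.all(out.data.var(axis=-1) <= arr.var(axis=-1) + 1e-12)

    def test_per_run_independence(self, rng):
        arr = rng.standard_normal((2, 2, 2, 40))
        both = detrend_timeseries(bold_from_array(arr, run_boundaries=(0, 20)))
        first = detrend_timeseries(bold_from_array(arr[..., :20]))
        assert np.allclose(both.data[..., :20], first.data)


class TestFitGLM:
    def _design(self, n, rng, p=3):
        X = np.column_stack([np.ones(n)] + [rng.standard_normal(n)
                                            for _ in range(p - 1)])
        return DesignMatrix(values=X,
                            column_labels=tuple(f"c{i}" for i in range(p)),
                            tr_s=2.0, run_boundaries=(0,))

    def test_noiseless_recovery_is_exact(self, rng):
        dm = self._design(30, rng)
        beta = np.array([1.0, -2.0, 0.5])
        Y = dm.values @ beta
        arr = np.tile(Y, (2, 2, 1, 1)).reshape(2, 2, 1, 30)
        res = fit_glm(bold_from_array(arr), dm)
        for i, lab in enumerate(dm.column_labels):
            assert np.allclose(res.betas[lab].values, beta[i], atol=1e-10)
        assert np.allclose(res.sigma2.values, 0.0, atol=1e-18)

    def test_matches_explicit_normal_equations(self, rng):
        """Single voxel, noisy: compare to a hand-rolled normal-equation solve."""
        dm = self._design(25, rng)
        y = dm.values @ np.array([0.3, 1.2, -0.7]) + rng.standard_normal(25)
        oracle = np.linalg.solve(dm.values.T @ dm.values, dm.values.T @ y)
        res = fit_glm(bold_from_array(y.reshape(1, 1, 1, 25)), dm)
        got = [res.betas[lab].values[0, 0, 0] for lab in dm.column_labels]
        assert np.allclose(got, oracle, atol=1e-10)
        rss = np.sum((y - dm.values @ oracle) ** 2)
        assert res.sigma2.values[0, 0, 0] == pytest.approx(rss / (25 - 3))

    def test_orthogonal_response_gives_zero_betas(self, rng):
        dm = self._design(24, rng, p=2)
        # build y orthogonal to both columns
        Q, _ = np.linalg.qr(dm.values)
        y = rng.standard_normal(24)
        y -= Q @ (Q.T @ y)
        res = fit_glm(bold_from_array(y.reshape(1, 1, 1, 24)), dm)
        assert abs(res.betas["c0"].values[0, 0, 0]) < 1e-10
        assert abs(res.betas["c1"].values[0, 0, 0]) < 1e-10

    def test_out_of_mask_is_nan(self, rng):
        dm = self._design(20, rng)
        arr = rng.standard_normal((2, 1, 1, 20))
        mask = np.array([True, False]).reshape(2, 1, 1)
        res = fit_glm(bold_from_array(arr, mask=mask), dm)
        assert np.isnan(res.betas["c0"].values[1, 0, 0])
        assert np.isfinite(res.betas["c0"].values[0, 0, 0])

    def test_rank_deficient_design_names_columns(self, rng):
        X = np.ones((20, 2))
        dm = DesignMatrix(values=X, column_labels=("a", "b"), tr_s=2.0,
                          run_boundaries=(0,))
        with pytest.raises(ValidationError, match="'a' and 'b'"):
            fit_glm(bold_from_array(rng.standard_normal((1, 1, 1, 20))), dm)


class TestContrastT:
    def _fit(self, rng, n=100, nvox=500, beta=0.0):
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        dm = DesignMatrix(values=X, column_labels=("intercept", "x"),
                          tr_s=2.0, run_boundaries=(0,))
        Y = beta * X[:, 1:2] + rng.standard_normal((n, nvox))
        arr = Y.T.reshape(nvox, 1, 1, n)
        return fit_glm(bold_from_array(arr), dm)

    def test_null_t_matches_student_distribution(self, rng):
        res = self._fit(rng)
        tmap = contrast_t(res, [0.0, 1.0])
        tvals = tmap.values[np.isfinite(tmap.values)]
        ks = stats.kstest(tvals, "t", args=(res.df,))
        assert ks.pvalue > 0.01

    def test_sign_flip(self, rng):
        res = self._fit(rng, nvox=10, beta=0.5)
        t_pos = contrast_t(res, [0.0, 1.0]).values
        t_neg = contrast_t(res, [0.0, -1.0]).values
        assert np.allclose(t_pos, -t_neg, equal_nan=True)

    def test_zero_variance_voxel_flagged_not_nan(self):
        n = 12
        X = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        dm = DesignMatrix(values=X, column_labels=("intercept", "x"),
                          tr_s=2.0, run_boundaries=(0,))
        Y = X @ np.array([1.0, 2.0])  # noiseless: sigma2 == 0
        res = fit_glm(bold_from_array(Y.reshape(1, 1, 1, n)), dm)
        tmap = contrast_t(res, [0.0, 1.0])
        assert not tmap.valid[0, 0, 0]
        assert np.isfinite(tmap.values[0, 0, 0])

    def test_zero_contrast_rejected(self, rng):
        res = self._fit(rng, nvox=2)
        with pytest.raises(ValidationError, match="zero"):
            contrast_t(res, [0.0, 0.0])


def _maps_from_values(vals):
    return [StatMap(values=v, stat_kind="beta") for v in vals]


class TestGroupDifference:
    def test_identical_groups_give_zero_t(self, rng):
        base = rng.standard_normal((4, 4, 3))
        maps = _maps_from_values([base] * 3 + [base] * 3)
        gmap = group_difference_map(maps, ["MS"] * 3 + ["HC"] * 3)
        assert np.allclose(np.nan_to_num(gmap.values), 0.0)

    def test_injected_offset_matches_analytic_expectation(self, rng):
        """Mean in-cluster t ~= delta / (sigma*sqrt(1/n1+1/n2)) over replicates."""
        n1, n2, delta, sigma = 12, 11, 1.0, 0.5
        expected = delta / (sigma * np.sqrt(1 / n1 + 1 / n2))
        tvals = []
        for _ in range(300):
            ms = delta + sigma * rng.standard_normal((n1, 2, 2, 1))
            hc = sigma * rng.standard_normal((n2, 2, 2, 1))
            maps = _maps_from_values(list(ms) + list(hc))
            gmap = group_difference_map(maps, ["MS"] * n1 + ["HC"] * n2)
            tvals.append(np.nanmean(gmap.values))
        # Student-t correction factor for E[1/s] is ~1+3/(4 df); allow sim error
        assert np.mean(tvals) == pytest.approx(expected, rel=0.1)

    def test_permuting_labels_gives_symmetric_t(self, rng):
        vals = rng.standard_normal((10, 3, 3, 2))
        maps = _maps_from_values(list(vals))
        t_all = []
        for _ in range(200):
            labels = np.array(["MS"] * 5 + ["HC"] * 5)
            rng.shuffle(labels)
            g = group_difference_map(maps, list(labels))
            t_all.append(np.nanmean(g.values))
        t_all = np.array(t_all)
        assert abs(np.mean(t_all)) < 2 * np.std(t_all) / np.sqrt(len(t_all)) + 0.05

    def test_df_accounts_for_covariates(self, rng):
        vals = rng.standard_normal((10, 2, 2, 2))
        maps = _maps_from_values(list(vals))
        labels = ["MS"] * 5 + ["HC"] * 5
        cov = rng.standard_normal((10, 2))
        g0 = group_difference_map(maps, labels)
        g2 = group_difference_map(maps, labels, covariates=cov)
        assert g0.df == 8
        assert g2.df == 6

    def test_equals_pooled_two_sample_t_without_covariates(self, rng):
        """Cross-check the regression route against scipy's two-sample t."""
        ms = rng.standard_normal((6, 2, 2, 1)) + 0.8
        hc = rng.standard_normal((5, 2, 2, 1))
        maps = _maps_from_values(list(ms) + list(hc))
        g = group_difference_map(maps, ["MS"] * 6 + ["HC"] * 5)
        sp = stats.ttest_ind(ms, hc, axis=0)
        assert np.allclose(g.values, sp.statistic, atol=1e-10)

    def test_grid_mismatch_rejected(self, rng):
        maps = _maps_from_values([rng.standard_normal((2, 2, 2))] * 2
                                 + [rng.standard_normal((3, 2, 2))] * 2)
        with pytest.raises(ValidationError):
            group_difference_map(maps, ["MS", "MS", "HC", "HC"])


class TestOlsFit:
    def test_statsmodels_cross_check(self, rng):
        """Independent route: statsmodels OLS per response column."""
        import statsmodels.api as sm

        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        Y = rng.standard_normal((40, 3))
        beta, sigma2, xtx_inv, df = ols_fit(X, Y)
        for j in range(3):
            fit = sm.OLS(Y[:, j], X).fit()
            assert np.allclose(beta[:, j], fit.params, atol=1e-10)
            assert sigma2[j] == pytest.approx(fit.mse_resid)
            assert df == int(fit.df_resid)
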