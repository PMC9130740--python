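"""Design-matrix construction, smoothing and first-level OLS fitting."""

import numpy as np
import pytest
from scipy import ndimage, stats

from nbrlifespan.events import EventSchedule
from nbrlifespan.glm import (
    BOLDDataset,
    DesignMatrix,
    FirstLevelGLM,
    MotionTrace,
    build_design_matrix,
    fit_timecourse_glm,
    gaussian_smooth,
    sampled_regressor,
    t_to_z,
)
from nbrlifespan.hrf import HRTimecourse, canonical_double_gamma, stretched_double_gamma
from nbrlifespan.atlas import toy_atlas
from nbrlifespan.synthetic import noiseless_region_signal, subject_from_age, synthesize_subject

from conftest import N_VOLUMES, TR


def _impulse_kernel(dt=0.05):
    samples = np.zeros(int(24.0 / dt) + 1)
    samples[0] = 1.0
    return HRTimecourse(samples=samples, dt=dt, window=24.0)


def _single_condition_schedule(onsets, run_length=200.0):
    return EventSchedule(
        onsets=np.asarray(onsets, float),
        durations=np.full(len(onsets), 0.05),
        conditions=tuple("audio" for _ in onsets),
        run_length=run_length,
    )


class TestBuildDesignMatrix:
    def test_impulse_kernel_reproduces_delta_train(self):
        sched = _single_condition_schedule([0.0])
        design = build_design_matrix(sched, _impulse_kernel(), tr=2.0, n_volumes=90)
        col = design.matrix[:, design.column_labels.index("audio")]
        expected = np.zeros(90)
        expected[0] = 1.0  # the event coincides with volume 0
        assert np.allclose(col, expected)

    def test_five_conditions_plus_motion_gives_eleven_columns(self, schedule):
        motion = MotionTrace(params=np.zeros((N_VOLUMES, 6)) + np.arange(N_VOLUMES)[:, None] * 1e-3)
        design = build_design_matrix(
            schedule, canonical_double_gamma(0.05, 32.0), TR, N_VOLUMES, motion=motion
        )
        assert design.n_regressors == 11

    def test_two_far_events_superpose(self):
        kernel = canonical_double_gamma(0.05, 32.0)
        both = _single_condition_schedule([10.0, 110.0])
        first = _single_condition_schedule([10.0])
        second = _single_condition_schedule([110.0])
        tr, nvol = 2.0, 100
        col = lambda s: build_design_matrix(s, kernel, tr, nvol).matrix[:, 0]
        assert np.allclose(col(both), col(first) + col(second), atol=1e-12)

    def test_event_past_run_end_rejected(self):
        sched = _single_condition_schedule([150.0], run_length=200.0)
        with pytest.raises(ValueError, match="beyond"):
            sampled_regressor(sched.onsets, sched.durations, _impulse_kernel(), 2.0, 50)


class TestGaussianSmooth:
    def _dataset(self, values):
        labels = np.zeros(values.shape[:3], dtype=np.int16)
        return BOLDDataset(values=values, tr=2.0, label_map=labels)

    def test_fwhm_zero_is_identity(self, rng):
        data = self._dataset(rng.normal(size=(8, 8, 4, 3)))
        assert gaussian_smooth(data, 0.0) is data

    def test_impulse_matches_dense_separable_oracle(self):
        values = np.zeros((9, 9, 9, 1))
        values[4, 4, 4, 0] = 1.0
        data = self._dataset(values)
        fwhm = 5.0
        out = gaussian_smooth(data, fwhm).values[..., 0]
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0  # 3 mm voxels
        oracle = ndimage.gaussian_filter(values[..., 0], sigma=sigma, mode="reflect")
        assert np.allclose(out, oracle, atol=1e-12)

    def test_volume_sum_conserved(self, rng):
        data = self._dataset(rng.normal(size=(10, 10, 6, 2)))
        out = gaussian_smooth(data, 5.0)
        for v in range(2):
            assert np.isclose(out.values[..., v].sum(), data.values[..., v].sum(), atol=1e-6)


class TestTToZ:
    def test_monotone_and_odd(self):
        t = np.linspace(-8, 8, 41)
        z = t_to_z(t, df=20)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(t_to_z(-t, df=20), -z, atol=1e-12)

    def test_matches_two_sided_tail_mapping(self):
        z = t_to_z(np.array([2.5]), df=10)[0]
        expected = stats.norm.isf(stats.t.sf(2.5, 10))
        assert np.isclose(z, expected)


class TestFitGlm:
    def _toy_dataset(self, schedule):
        spec = subject_from_age("sub-g", 25.8, seed=0, jitter=False)
        data, _ = synthesize_subject(spec, schedule)
        return spec, data

    def test_noiseless_fit_recovers_exact_betas(self, rng):
        X = rng.normal(size=(40, 3))
        b = np.array([1.5, -2.0, 0.25])
        y = X @ b
        design = DesignMatrix(
            matrix=X, column_labels=["a", "b", "c"],
            contrasts={"first": np.array([1.0, 0, 0])}, tr=2.0,
        )
        out = fit_timecourse_glm(y, design)
        assert np.isclose(out["first"][0], 1.5, atol=1e-10)

    def test_six_point_toy_regression_t_statistic(self):
        # closed-form simple regression oracle computed by hand formulas
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.8])
        X = np.column_stack([np.ones(6), x])
        design = DesignMatrix(
            matrix=X, column_labels=["const", "x"],
            contrasts={"slope": np.array([0.0, 1.0])}, tr=1.0,
        )
        beta, vcb, z = fit_timecourse_glm(y, design)["slope"]
        bhat = (np.sum((x - x.mean()) * (y - y.mean()))) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() - bhat * x.mean()) - bhat * x
        s2 = resid @ resid / 4
        se = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        assert np.isclose(beta, bhat, atol=1e-12)
        assert np.isclose(beta / np.sqrt(vcb), bhat / se, atol=1e-10)

    def test_negative_contrast_z_is_negated(self, schedule):
        spec, data = self._toy_dataset(schedule)
        # add deterministic pseudo-noise so variance is non-degenerate
        rng = np.random.default_rng(0)
        data = BOLDDataset(
            values=data.values + rng.normal(0, 0.005, size=data.values.shape),
            tr=data.tr, label_map=data.label_map,
        )
        design = build_design_matrix(
            schedule, canonical_double_gamma(0.05, 32.0), TR, N_VOLUMES, drift_order=2
        )
        res = FirstLevelGLM(data, design).fit()
        zp, zn = res.z_maps["pos_mean"], res.z_maps["neg_mean"]
        ok = np.isfinite(zp)
        assert np.allclose(zp[ok], -zn[ok], atol=1e-10)
        assert res.degrees_of_freedom == N_VOLUMES - design.n_regressors

    def test_matched_kernel_recovers_injected_amplitude(self, schedule):
        spec = subject_from_age("sub-m", 82.6, seed=0, jitter=False)
        y = noiseless_region_signal(spec, schedule, "iSM1")
        kernel = stretched_double_gamma(0.05, 32.0, spec.region_params["iSM1"].time_to_peak)
        design = build_design_matrix(schedule, kernel, TR, N_VOLUMES, drift_order=2)
        beta = fit_timecourse_glm(y, design)["pos_mean"][0]
        amp = spec.region_params["iSM1"].amplitude
        assert abs(beta - amp) / abs(amp) < 1e-8

    def test_canonical_kernel_attenuates_late_response(self, schedule):
        # late (18 s) response fitted with the ~5 s canonical kernel
        spec = subject_from_age("sub-o", 82.6, seed=0, jitter=False)
        y = noiseless_region_signal(spec, schedule, "iSM1")
        matched = stretched_double_gamma(0.05, 32.0, spec.region_params["iSM1"].time_to_peak)
        canonical = canonical_double_gamma(0.05, 32.0)
        d_m = build_design_matrix(schedule, matched, TR, N_VOLUMES, drift_order=2)
        d_c = build_design_matrix(schedule, canonical, TR, N_VOLUMES, drift_order=2)
        b_m = abs(fit_timecourse_glm(y, d_m)["pos_mean"][0])
        b_c = abs(fit_timecourse_glm(y, d_c)["pos_mean"][0])
        assert b_c < b_m

    def test_rank_deficient_design_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.column_stack([X, X[:, 0]])
        design = DesignMatrix(
            matrix=X, column_labels=["a", "b", "c"],
            contrasts={"c0": np.array([1.0, 0, 0])}, tr=1.0,
        )
        values = rng.normal(size=(2, 2, 1, 20))
        data = BOLDDataset(values=values, tr=1.0, label_map=np.zeros((2, 2, 1), np.int16))
        with pytest.raises(ValueError, match="rank"):
            FirstLevelGLM(data, design).fit()

    def test_degenerate_voxels_flagged_invalid(self, rng):
        # constant voxel: zero residual variance, nonzero contrast → NaN Z
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        design = DesignMatrix(
            matrix=X, column_labels=["const", "x"],
            contrasts={"const": np.array([1.0, 0.0])}, tr=1.0,
        )
        values = np.zeros((2, 1, 1, 20))
        values[0, 0, 0] = 3.0  # perfectly constant voxel
        values[1, 0, 0] = rng.normal(size=20)
        data = BOLDDataset(values=values, tr=1.0, label_map=np.zeros((2, 1, 1), np.int16))
        res = FirstLevelGLM(data, design).fit()
        assert not res.valid_mask[0, 0, 0]
        assert np.isnan(res.z_maps["const"][0, 0, 0])
        assert res.valid_mask[1, 0, 0]

    def test_summary_mentions_df_and_contrasts(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        design = DesignMatrix(
            matrix=X, column_labels=["const", "x"],
            contrasts={"const": np.array([1.0, 0.0])}, tr=1.0,
        )
        data = BOLDDataset(
            values=rng.normal(size=(2, 2, 1, 20)), tr=1.0,
            label_map=np.zeros((2, 2, 1), np.int16),
        )
        text = FirstLevelGLM(data, design).fit().summary()
        assert "df: 18" in text and "const" in text
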