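"""Preprocessing steps: dummy removal, DVARS, regression, smoothing,
interpolation, filtering, and the fixed pipeline orderings."""

import numpy as np
import pytest
from scipy.stats import norm

from dfncflow.preprocess import (
    PIPELINE_PLANS,
    PipelineConfig,
    SpikeSet,
    bandpass_filter,
    build_regressors,
    detect_spikes_dvars,
    drop_dummy_volumes,
    interpolate_spikes,
    regress_nuisance,
    smooth_spatial,
)
from dfncflow.synthgen import (
    RealignmentParams,
    VolumeSeries,
    generate_cohort,
    motion_gradient_map,
    synth_motion_trace,
)
from conftest import two_state_config


def _noise_series(rng, frames=80, shape=(6, 6, 6)):
    return VolumeSeries(1000.0 + rng.normal(0, 1.0, size=(*shape, frames)))


class TestDropDummies:
    def test_150_frames_minus_5_dummies_keeps_145(self, rng):
        out = drop_dummy_volumes(_noise_series(rng, frames=150), 5)
        assert out.n_frames == 145

    def test_zero_dummies_is_identity(self, rng):
        s = _noise_series(rng)
        out = drop_dummy_volumes(s, 0)
        assert np.array_equal(out.intensities, s.intensities)

    def test_index_arithmetic(self, rng):
        s = _noise_series(rng, frames=10)
        out = drop_dummy_volumes(s, 3)
        assert out.n_frames == 7
        assert np.array_equal(out.intensities[..., 0], s.intensities[..., 3])

    def test_dropping_all_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            drop_dummy_volumes(_noise_series(rng, frames=10), 10)


class TestDvars:
    def test_planted_deviation_flagged_at_all_thresholds(self, rng):
        s = _noise_series(rng)
        s.intensities[..., 40] += 10.0 * s.flatten_voxels().std()
        for thr in (2.5, 3.0, 4.0):
            spikes = detect_spikes_dvars(s, thr)
            assert {40, 41} & set(spikes.frames.tolist()), thr

    def test_threshold_monotonicity(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s = _noise_series(rng)
            s.intensities[..., rng.integers(1, 79, size=3)] += rng.normal(0, 5)
            sets = {t: set(detect_spikes_dvars(s, t).frames.tolist())
                    for t in (2.5, 3.0, 4.0)}
            assert sets[4.0] <= sets[3.0] <= sets[2.5]

    def test_constant_series_yields_empty_spikeset_with_warning(self):
        s = VolumeSeries(np.full((4, 4, 4, 30), 500.0))
        with pytest.warns(UserWarning, match="constant"):
            spikes = detect_spikes_dvars(s, 3.0)
        assert spikes.n_spikes == 0

    def test_stationary_noise_flag_rate_tracks_gaussian_tail(self):
        """Monte-Carlo oracle: on stationary noise the DVARS z-score behaves
        roughly normally, so the flag rate at threshold t should be on the
        order of the Gaussian upper-tail mass."""
        counts = {2.5: 0, 4.0: 0}
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            s = VolumeSeries(1000.0 + rng.normal(0, 1.0, size=(5, 5, 5, 100)))
            total += s.n_frames - 1
            for t in counts:
                counts[t] += detect_spikes_dvars(s, t).n_spikes
        rate_25 = counts[2.5] / total
        assert 0.2 * norm.sf(2.5) < rate_25 < 5 * norm.sf(2.5)
        assert counts[4.0] / total < 10 * norm.sf(4.0) + 1e-3

    def test_frame_zero_never_flagged(self, rng):
        s = _noise_series(rng)
        s.intensities[..., 0] += 50.0
        spikes = detect_spikes_dvars(s, 2.5)
        assert 0 not in spikes.frames


class TestRegressors:
    def test_motion_only_has_six_columns(self):
        realign = synth_motion_trace(50, 0.5, seed=0)
        reg = build_regressors(realign, parts={"motion"})
        assert reg.values.shape == (50, 6)

    def test_all_parts_with_two_spikes_gives_17_columns(self):
        realign = synth_motion_trace(50, 0.5, seed=0)
        spikes = SpikeSet(np.array([10, 40]), 3.0, np.zeros(50))
        reg = build_regressors(realign, spikes)
        assert reg.values.shape[1] == 3 + 6 + 6 + 2
        assert reg.labels[:3] == ["trend-1", "trend-2", "trend-3"]

    def test_spike_column_is_unit_indicator(self):
        spikes = SpikeSet(np.array([40]), 3.0, np.zeros(50))
        reg = build_regressors(None, spikes, parts={"spikes"}, n_frames=50)
        col = reg.values[:, reg.labels.index("spike-40")]
        assert col.sum() == 1.0 and col[40] == 1.0

    def test_derivative_is_backward_difference_zero_at_frame_zero(self):
        realign = RealignmentParams(np.outer(np.arange(10.0), np.ones(6)))
        reg = build_regressors(realign, parts={"derivatives"})
        assert np.all(reg.values[0] == 0)
        assert np.allclose(reg.values[1:], 1.0)

    def test_mismatched_length_rejected(self):
        realign = synth_motion_trace(50, 0.5, seed=0)
        with pytest.raises(ValueError):
            build_regressors(realign, n_frames=49)


class TestRegression:
    def test_signal_equal_to_regressor_column_zeroed(self):
        realign = synth_motion_trace(60, 0.5, seed=1)
        reg = build_regressors(realign, parts={"motion"})
        signal = reg.values[:, 2:3].copy()
        resid = regress_nuisance(signal, reg)
        assert np.max(np.abs(resid)) < 1e-10

    def test_empty_regressors_mean_center(self, rng):
        reg = build_regressors(None, parts=set(), n_frames=40)
        y = rng.normal(size=(40, 3)) + 7.0
        resid = regress_nuisance(y, reg)
        np.testing.assert_allclose(resid, y - y.mean(axis=0), atol=1e-12)

    def test_residuals_orthogonal_to_regressors(self, rng):
        realign = synth_motion_trace(80, 0.8, seed=2)
        spikes = SpikeSet(np.array([12, 55]), 3.0, np.zeros(80))
        reg = build_regressors(realign, spikes)
        y = rng.normal(size=(80, 10))
        resid = regress_nuisance(y, reg)
        for j in range(reg.values.shape[1]):
            x = reg.values[:, j]
            bound = 1e-8 * np.linalg.norm(x) * np.linalg.norm(resid, axis=0)
            assert np.all(np.abs(resid.T @ x) < np.maximum(bound, 1e-12))

    def test_planted_motion_leak_removed_from_volume(self):
        cfg = two_state_config(n_pairs=1, motion_coupling=2.0, motion_amp_mm=1.0,
                               noise_sd=0.05, spike_rate_per_min=0.0, seed=21)
        cohort = generate_cohort(cfg)
        subj = cohort.subjects[0]
        leak = subj.realignment.translations.sum(axis=1)
        grad = motion_gradient_map(cfg.grid_shape)
        voxel = np.argmax(np.abs(grad))
        before = subj.volume.flatten_voxels()[voxel]
        assert abs(np.corrcoef(before, leak)[0, 1]) > 0.5
        reg = build_regressors(subj.realignment, parts={"trends", "motion", "derivatives"})
        cleaned = regress_nuisance(subj.volume, reg)
        after = cleaned.flatten_voxels()[voxel]
        assert abs(np.corrcoef(after, leak)[0, 1]) < 0.05

    def test_rank_deficient_design_warns(self, rng):
        values = np.ones((30, 2))
        reg = build_regressors(None, parts=set(), n_frames=30)
        reg.values = np.column_stack([np.arange(30.0), np.arange(30.0)])
        reg.labels = ["a", "b"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_nuisance(rng.normal(size=(30, 2)), reg)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        s = _noise_series(rng)
        out = smooth_spatial(s, 0.0)
        assert np.array_equal(out.intensities, s.intensities)

    def test_constant_frame_unchanged(self):
        s = VolumeSeries(np.full((8, 8, 8, 3), 42.0))
        out = smooth_spatial(s, 6.0)
        np.testing.assert_allclose(out.intensities, 42.0, atol=1e-10)

    def test_impulse_half_maximum_at_fwhm_radius(self):
        # 1 mm voxels and FWHM 8 mm: half maximum expected 4 voxels from center
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_spatial(VolumeSeries(data, voxel_mm=(1, 1, 1)), fwhm_mm=8.0)
        prof = out.intensities[:, 10, 10, 0]
        assert prof[14] / prof[10] == pytest.approx(0.5, abs=0.02)

    def test_frame_mean_preserved(self, rng):
        s = _noise_series(rng, frames=4, shape=(10, 10, 10))
        out = smooth_spatial(s, 6.0)
        np.testing.assert_allclose(
            out.intensities.mean(axis=(0, 1, 2)),
            s.intensities.mean(axis=(0, 1, 2)), rtol=1e-6)


class TestInterpolation:
    def test_empty_spikeset_is_identity(self, rng):
        tc = rng.normal(size=(60, 4))
        spikes = SpikeSet(np.empty(0, dtype=int), 3.0, np.zeros(60))
        assert np.array_equal(interpolate_spikes(tc, spikes), tc)

    def test_cubic_polynomial_restored_exactly(self):
        t = np.linspace(0, 1, 50)
        tc = (2 * t**3 - t**2 + 3 * t - 1)[:, None]
        corrupted = tc.copy()
        corrupted[25] = 0.0
        spikes = SpikeSet(np.array([25]), 3.0, np.zeros(50))
        restored = interpolate_spikes(corrupted, spikes)
        assert abs(restored[25, 0] - tc[25, 0]) < 1e-6

    def test_sinusoid_restoration_error_below_5_percent(self):
        t = np.arange(100)
        tc = np.sin(2 * np.pi * t / 40)[:, None]
        corrupted = tc.copy()
        frames = np.array([30, 55, 70])
        corrupted[frames] = 0.0
        spikes = SpikeSet(frames, 3.0, np.zeros(100))
        restored = interpolate_spikes(corrupted, spikes)
        assert np.max(np.abs(restored[frames] - tc[frames])) < 0.05

    def test_edge_spike_warns(self, rng):
        tc = rng.normal(size=(30, 2))
        spikes = SpikeSet(np.array([29]), 3.0, np.zeros(30))
        with pytest.warns(UserWarning, match="edge"):
            interpolate_spikes(tc, spikes)


class TestBandpass:
    def test_constant_removed(self):
        tc = np.full((200, 2), 5.0)
        out = bandpass_filter(tc, tr_s=2.0)
        assert np.max(np.abs(out)) < 1e-6

    def test_passband_center_preserved(self):
        t = np.arange(400) * 2.0
        tc = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = bandpass_filter(tc, tr_s=2.0)
        mid = slice(50, 350)  # avoid edge transients
        ratio = out[mid].std() / tc[mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_near_nyquist_attenuated(self):
        t = np.arange(400) * 2.0
        tc = np.cos(2 * np.pi * 0.25 * t)[:, None]  # alternating at Nyquist
        out = bandpass_filter(tc, tr_s=2.0)
        mid = slice(50, 350)  # avoid zero-phase edge transients
        assert out[mid].std() / tc[mid].std() < 0.1

    def test_filter_nearly_idempotent_in_passband(self):
        t = np.arange(400) * 2.0
        tc = np.sin(2 * np.pi * 0.05 * t)[:, None]
        once = bandpass_filter(tc, tr_s=2.0)
        twice = bandpass_filter(once, tr_s=2.0)
        mid = slice(50, 350)
        assert np.max(np.abs(twice[mid] - once[mid])) < 0.1 * tc[mid].std()

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((50, 1)), low_hz=0.01, high_hz=0.3, tr_s=2.0)


class TestPipelinePlans:
    def test_pb_plan_matches_definition(self):
        cfg = PipelineConfig("PB")
        assert cfg.step_plan == ("MotReg", "Smoothing", "gICA", "SpkReg", "Interp", "Filter")

    def test_pd_regresses_after_gica(self):
        plan = PipelineConfig("PD").step_plan
        assert plan.index("SpkMotReg") > plan.index("gICA")

    def test_pa_regresses_before_smoothing(self):
        plan = PipelineConfig("PA").step_plan
        assert plan.index("SpkMotReg") < plan.index("Smoothing")

    def test_only_four_orderings_constructible(self):
        assert set(PIPELINE_PLANS) == {"PA", "PB", "PC", "PD"}
        with pytest.raises(ValueError):
            PipelineConfig("PE")

    def test_all_plans_end_with_interp_then_filter(self):
        for plan in PIPELINE_PLANS.values():
            assert plan[-2:] == ("Interp", "Filter")
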