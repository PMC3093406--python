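"""VSD pipeline stages against loop oracles, plus threshold monotonicity and
null calibration of the activated-pixel statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import naive
from vsdquant import synth, vsd
from vsdquant.core import (
    AcquisitionSpec,
    IncompatibleInputsError,
    InsufficientDataError,
    InvalidParameterError,
    OutOfBoundsError,
    VSDMovie,
)
from vsdquant.pipeline import VSDConfig, amplitude_movie, analyze_slice


def random_movie(spec, seed=0, mean=100.0, sd=3.0):
    return synth.make_baseline_movie(spec, baseline_mean=mean, noise_sd=sd, seed=seed)


class TestSmoothing:
    def test_constant_movie_unchanged(self, small_spec):
        m = synth.make_baseline_movie(small_spec, baseline_mean=4.2, noise_sd=0.0)
        out = vsd.smooth_movie(m)
        assert np.allclose(out.frames, 4.2, atol=1e-12)

    def test_impulse_response_equals_normalized_kernel(self, small_spec):
        frames = np.zeros(small_spec.shape)
        frames[20, 6, 5] = 1.0  # interior in space and time
        out = vsd.smooth_movie(VSDMovie(frames=frames, spec=small_spec))
        w1 = naive.gaussian_weights_1d(3, 1.0)
        expected = np.einsum("t,i,j->tij", w1, w1, w1)
        got = out.frames[19:22, 5:8, 4:7]
        assert np.allclose(got, expected, atol=1e-12)
        assert out.frames.sum() == pytest.approx(1.0)  # weights sum to 1

    def test_matches_naive_loop_convolution(self, small_spec):
        m = random_movie(small_spec, seed=1)
        out = vsd.smooth_movie(m)
        expected = naive.temporal_smooth(naive.spatial_smooth(m.frames))
        assert np.allclose(out.frames, expected, atol=1e-9)

    def test_interior_mean_preserved(self, small_spec):
        m = random_movie(small_spec, seed=2)
        out = vsd.smooth_movie(m)
        # away from all boundaries the kernel is a weighted average: global
        # interior sums agree to the extent boundary effects cancel exactly
        assert out.frames.mean() == pytest.approx(m.frames.mean(), rel=1e-3)

    @pytest.mark.parametrize("kwargs", [{"spatial_kernel_px": 4}, {"temporal_kernel_frames": 2}])
    def test_even_kernel_rejected(self, small_movie, kwargs):
        with pytest.raises(InvalidParameterError):
            vsd.smooth_movie(small_movie, **kwargs)


class TestBaselineStats:
    def test_constant_movie(self, small_spec):
        m = synth.make_baseline_movie(small_spec, baseline_mean=3.0, noise_sd=0.0)
        b = vsd.baseline_stats(m, n_frames=10)
        assert np.all(b.mean_map == 3.0)
        assert np.all(b.sd_map == 0.0)
        assert b.window == (0, 10)

    def test_default_window_is_50_frames(self):
        spec = AcquisitionSpec(n_frames=120)
        m = random_movie(spec, seed=0)
        b = vsd.baseline_stats(m)
        assert b.window == (0, 50)

    def test_matches_naive_two_pass(self):
        spec = AcquisitionSpec(frame_height=4, frame_width=4, n_frames=6, stim_frame=5, n_baseline_frames=5)
        m = random_movie(spec, seed=3)
        b = vsd.baseline_stats(m, n_frames=5)
        mean, sd = naive.mean_sd_maps(m.frames, 0, 5)
        assert np.allclose(b.mean_map, mean, atol=1e-9)
        assert np.allclose(b.sd_map, sd, atol=1e-9)

    def test_too_few_prestim_frames_rejected(self, small_movie):
        with pytest.raises(InsufficientDataError):
            vsd.baseline_stats(small_movie, n_frames=11)


class TestAmplitudeMap:
    def test_centering_and_scaling(self, small_spec):
        m = random_movie(small_spec, seed=4)
        b = vsd.baseline_stats(m, n_frames=10)
        amp = vsd.amplitude_map(m, b)
        # a pixel exactly at its baseline mean maps to 0 SD; mean + 2 sd to 2 SD
        frames = m.frames.copy()
        frames[15] = b.mean_map
        frames[16] = b.mean_map + 2.0 * b.sd_map
        amp = vsd.amplitude_map(m.with_frames(frames), b)
        assert np.allclose(amp.values[15], 0.0, atol=1e-12)
        assert np.allclose(amp.values[16], 2.0, atol=1e-9)

    def test_peak_recovery_with_attenuation_bound(self):
        # inject 3 SD; after smoothing the recovered peak must sit within the
        # attenuation of the naive-smoothed noiseless signal, up to noise
        spec = AcquisitionSpec(frame_height=16, frame_width=16, n_frames=90, stim_frame=50)
        noise_sd = 1.0
        m = synth.make_baseline_movie(spec, baseline_mean=1000.0, noise_sd=noise_sd, seed=5)
        truth = synth.ActivationGroundTruth(
            center=(8.0, 8.0), onset_frame=52, peak_amplitude=3.0, spatial_sigma=3.0
        )
        m2, _ = synth.inject_activation(m, truth, noise_sd)
        amp = amplitude_movie(m2, VSDConfig())
        signal = synth.activation_signal(spec, truth, noise_sd)
        expected_peak = naive.temporal_smooth(naive.spatial_smooth(signal)).max() / noise_sd
        got_peak = amp.values[50:, 8, 8].max()
        assert got_peak == pytest.approx(expected_peak, abs=0.5)

    def test_shape_mismatch_rejected(self, small_movie):
        b = vsd.baseline_stats(small_movie, n_frames=10)
        other = AcquisitionSpec(frame_height=5, frame_width=5, n_frames=20, stim_frame=10, n_baseline_frames=5)
        with pytest.raises(IncompatibleInputsError):
            vsd.amplitude_map(random_movie(other), b)

    def test_zero_variance_pixels_floored_and_flagged(self, small_spec):
        frames = np.full(small_spec.shape, 10.0)
        frames[20, 3, 3] = 11.0
        m = VSDMovie(frames=frames, spec=small_spec)
        b = vsd.baseline_stats(m, n_frames=10)
        amp = vsd.amplitude_map(m, b)
        assert amp.floored_mask.all()
        assert np.all(np.isfinite(amp.values))


class TestDeltaIOverI:
    def test_trivial_percentages(self, small_spec):
        m = synth.make_baseline_movie(small_spec, baseline_mean=50.0, noise_sd=0.0)
        b = vsd.baseline_stats(m, n_frames=10)
        d = vsd.delta_i_over_i(m, b)
        assert np.allclose(d.values, 0.0)
        d2 = vsd.delta_i_over_i(m.with_frames(m.frames * 1.01), b)
        assert np.allclose(d2.values, 1.0, atol=1e-9)

    def test_matches_naive_loops(self):
        spec = AcquisitionSpec(frame_height=4, frame_width=4, n_frames=8, stim_frame=5, n_baseline_frames=5)
        m = random_movie(spec, seed=6)
        b = vsd.baseline_stats(m, n_frames=5)
        d = vsd.delta_i_over_i(m, b)
        assert np.allclose(d.values, naive.delta_i_over_i(m.frames, b.mean_map), atol=1e-9)

    def test_nonpositive_mean_rejected(self, small_spec):
        frames = np.zeros(small_spec.shape)
        m = VSDMovie(frames=frames, spec=small_spec)
        b = vsd.baseline_stats(m, n_frames=10)
        with pytest.raises(InvalidParameterError):
            vsd.delta_i_over_i(m, b)


class TestActivatedPixels:
    def _amp(self, spec, values):
        return vsd.AmplitudeMovie(values=values, spec=spec)

    def test_null_frame_zero_activation(self, small_spec):
        amp = self._amp(small_spec, np.zeros(small_spec.shape))
        res = vsd.activated_pixels(amp, 5)
        assert res.activation_size == 0.0

    def test_exact_count_gives_exact_percentage(self):
        # 264 of 5280 pixels at or above threshold -> 5.0% of the frame
        spec = AcquisitionSpec(n_frames=60, stim_frame=50)
        values = np.zeros(spec.shape)
        flat = values[55].ravel()
        flat[:264] = 1.5
        res = vsd.activated_pixels(self._amp(spec, values), 55, threshold_sd=1.0)
        assert res.activation_size == 5.0
        assert naive.count_at_least(values[55], 1.0) == 264

    def test_display_threshold_supported(self, small_spec):
        values = np.zeros(small_spec.shape)
        values[12, 0, 0] = 1.05  # above 1.0, below 1.1
        amp = self._amp(small_spec, values)
        assert vsd.activated_pixels(amp, 12, vsd.DEFAULT_THRESHOLD_SD).activation_size > 0
        assert vsd.activated_pixels(amp, 12, vsd.DISPLAY_THRESHOLD_SD).activation_size == 0

    def test_excluded_pixels_do_not_count_but_frame_size_does(self, small_spec):
        values = np.ones(small_spec.shape) * 2.0
        excl = np.zeros((small_spec.frame_height, small_spec.frame_width), dtype=bool)
        excl[:6] = True
        res = vsd.activated_pixels(self._amp(small_spec, values), 0, exclusion_mask=excl)
        assert res.activation_size == pytest.approx(50.0)

    def test_frame_out_of_range_rejected(self, small_spec):
        amp = self._amp(small_spec, np.zeros(small_spec.shape))
        with pytest.raises(OutOfBoundsError):
            vsd.activated_pixels(amp, 40)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold(self, seed):
        spec = AcquisitionSpec(frame_height=8, frame_width=8, n_frames=12, stim_frame=10, n_baseline_frames=10)
        values = np.random.default_rng(seed).normal(size=spec.shape)
        amp = self._amp(spec, values)
        sizes = [
            vsd.activated_pixels(amp, 3, threshold_sd=t).activation_size
            for t in (0.25, 0.5, 1.0, 1.1, 1.5, 2.0, 3.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestNullCalibration:
    def test_unsmoothed_noise_matches_gaussian_tail(self):
        # fraction of pure-noise pixels >= 1 SD ~ upper-tail P(Z >= 1)
        spec = AcquisitionSpec(n_frames=150, stim_frame=50)
        m = synth.make_baseline_movie(spec, seed=8)
        amp = amplitude_movie(m, VSDConfig(smooth=False))
        frac = np.mean(amp.values[50:] >= 1.0)
        assert frac == pytest.approx(0.1587, abs=0.01)

    def test_smoothing_reduces_noise_exceedance(self):
        spec = AcquisitionSpec(n_frames=150, stim_frame=50)
        m = synth.make_baseline_movie(spec, seed=8)
        frac_raw = np.mean(amplitude_movie(m, VSDConfig(smooth=False)).values[50:] >= 1.0)
        frac_smooth = np.mean(amplitude_movie(m, VSDConfig()).values[50:] >= 1.0)
        assert frac_smooth < frac_raw / 10


class TestResponseAmplitude:
    def test_null_movie_response_near_false_positive_floor(self):
        spec = AcquisitionSpec(n_frames=200, stim_frame=50)
        m = synth.make_baseline_movie(spec, seed=9)
        resp, _ = analyze_slice(m, VSDConfig(post_window_frames=100))
        assert resp.response < 0.5  # percent of frame

    def test_monotone_in_signal_amplitude(self):
        spec = AcquisitionSpec(frame_height=24, frame_width=32, n_frames=130, stim_frame=50)
        base = synth.make_baseline_movie(spec, seed=10)
        responses = []
        for amp_sd in (4.0, 8.0):
            truth = synth.ActivationGroundTruth(
                center=(12, 16), onset_frame=52, peak_amplitude=amp_sd, spatial_sigma=4.0
            )
            m, _ = synth.inject_activation(base, truth, synth.DEFAULT_NOISE_SD)
            r, _ = analyze_slice(m, VSDConfig(post_window_frames=60))
            responses.append(r.response)
        assert responses[1] > responses[0]

    def test_artifact_exclusion_removes_artifact_contribution(self):
        spec = AcquisitionSpec(frame_height=24, frame_width=32, n_frames=130, stim_frame=50)
        m = synth.make_baseline_movie(spec, seed=11)
        m = synth.inject_stimulus_artifact(m, (12, 16), radius=2.0, amplitude=25 * 8.0)
        r, _ = analyze_slice(m, VSDConfig(post_window_frames=60))
        assert r.response < 0.5

    def test_empty_window_rejected(self, small_movie):
        amp = amplitude_movie(small_movie, VSDConfig(n_baseline_frames=10))
        with pytest.raises(InvalidParameterError):
            vsd.response_amplitude(amp, post_window_frames=0)

    def test_reduction_method_recorded(self, small_movie):
        amp = amplitude_movie(small_movie, VSDConfig(n_baseline_frames=10))
        r = vsd.response_amplitude(amp, post_window_frames=20, reduction="mean_activation_size")
        assert r.method == "mean_activation_size"


class TestPoolSites:
    def _amp(self, spec, values):
        return vsd.AmplitudeMovie(values=values, spec=spec)

    def test_single_site_identity(self, small_spec, rng):
        a = self._amp(small_spec, rng.normal(size=small_spec.shape))
        pooled = vsd.pool_sites([a])
        assert np.array_equal(pooled.values, a.values)

    def test_mean_mode_idempotent_on_identical_inputs(self, small_spec, rng):
        v = rng.normal(size=small_spec.shape)
        pooled = vsd.pool_sites([self._amp(small_spec, v), self._amp(small_spec, v.copy())])
        assert np.allclose(pooled.values, v, atol=1e-12)
        assert pooled.pooling == {"method": "mean", "n_sites": 2}

    def test_max_mode_keeps_disjoint_active_pixels(self, small_spec):
        a = np.zeros(small_spec.shape)
        b = np.zeros(small_spec.shape)
        a[5, 2, 2] = 3.0
        b[5, 9, 7] = 3.0
        pooled = vsd.pool_sites([self._amp(small_spec, a), self._amp(small_spec, b)], method="max")
        expected = np.maximum(a, b)
        assert np.array_equal(pooled.values, expected)
        assert pooled.values[5, 2, 2] == 3.0 and pooled.values[5, 9, 7] == 3.0

    def test_shape_mismatch_rejected(self, small_spec, rng):
        other = AcquisitionSpec(frame_height=5, frame_width=5, n_frames=40, stim_frame=10, n_baseline_frames=10)
        with pytest.raises(IncompatibleInputsError):
            vsd.pool_sites([
                self._amp(small_spec, rng.normal(size=small_spec.shape)),
                self._amp(other, rng.normal(size=other.shape)),
            ])


class TestPairNormalization:
    def _resp(self, x, condition="control"):
        return vsd.SliceResponse(slice_id="s", response=x, condition=condition)

    def test_identity_and_null_numerator(self):
        assert vsd.normalize_pair(self._resp(3.0, "treated"), self._resp(3.0)) == 100.0
        assert vsd.normalize_pair(self._resp(0.0, "treated"), self._resp(3.0)) == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(InvalidParameterError):
            vsd.normalize_pair(self._resp(1.0, "treated"), self._resp(0.0))

    def test_summary_arithmetic(self):
        s = vsd.summarize_pairs([100.0, 100.0, 100.0])
        assert s.mean == 100.0 and s.se == 0.0
        s2 = vsd.summarize_pairs([150.0, 180.0])
        assert s2.mean == pytest.approx(165.0)
        assert s2.se == pytest.approx(15.0)

    def test_summary_runs_selected_test(self):
        s = vsd.summarize_pairs(
            [150.0, 160.0, 170.0],
            test="mann_whitney",
            treated_responses=[3.0, 3.2, 3.4],
            control_responses=[2.0, 2.1, 2.2],
        )
        assert s.test.test_name == "mann_whitney"
        assert 0.0 <= s.test.p_value <= 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            vsd.summarize_pairs([100.0])


class TestTrialAveraging:
    def test_average_of_identical_trials_is_identity(self, small_movie):
        avg = vsd.average_trials([small_movie, small_movie])
        assert np.allclose(avg.frames, small_movie.frames)

    def test_average_reduces_noise(self, small_spec):
        trials = [synth.make_baseline_movie(small_spec, noise_sd=4.0, seed=s) for s in range(8)]
        avg = vsd.average_trials(trials)
        assert avg.frames.std() < trials[0].frames.std() / 2
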