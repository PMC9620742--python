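"""Motion index, LOESS, ΔF/F₀, onset detection, alignment, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from motorpop.signal_prep import (
    MotionIndexSeries,
    align_trials,
    compute_dff,
    compute_motion_index,
    detect_motion_onset,
    loess_smooth,
    resample_trials_fixed_length,
)
from motorpop.synthgen import SynthConfig, generate_session


def brute_force_motion_index(frames, mask):
    """Independent oracle: explicit pixel loop."""
    out = []
    for f in range(frames.shape[0] - 1):
        s = 0.0
        for i in range(frames.shape[1]):
            for j in range(frames.shape[2]):
                if mask[i, j]:
                    s += (float(frames[f + 1, i, j]) - float(frames[f, i, j])) ** 2
        out.append(s)
    return np.array(out)


class TestMotionIndex:
    def test_identical_frames_give_zero(self):
        frames = np.ones((3, 4, 4))
        mi = compute_motion_index(frames, np.ones((4, 4), bool))
        np.testing.assert_array_equal(mi.values, 0.0)

    def test_single_pixel_difference_squares(self):
        frames = np.zeros((2, 4, 4))
        frames[1, 2, 2] = 3.0
        mi = compute_motion_index(frames, np.ones((4, 4), bool))
        assert mi.values[0] == 9.0

    def test_masked_pixels_excluded(self):
        frames = np.zeros((2, 4, 4))
        frames[1, 0, 0] = 5.0
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        mi = compute_motion_index(frames, mask)
        assert mi.values[0] == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hst.integers(0, 2**31 - 1), hst.integers(2, 50),
           hst.integers(2, 32), hst.integers(2, 32))
    def test_matches_brute_force_oracle(self, seed, n, h, w):
        r = np.random.default_rng(seed)
        frames = r.integers(0, 255, size=(min(n, 8), h, w)).astype(float)
        mask = r.random((h, w)) > 0.3
        if not mask.any():
            mask[0, 0] = True
        mi = compute_motion_index(frames, mask)
        np.testing.assert_allclose(mi.values, brute_force_motion_index(frames, mask))

    def test_errors(self):
        with pytest.raises(ValueError, match="2 frames"):
            compute_motion_index(np.zeros((1, 4, 4)), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="mask"):
            compute_motion_index(np.zeros((2, 4, 4)), np.zeros((4, 4), bool))

    def test_series_rejects_negative_values(self):
        with pytest.raises(ValueError):
            MotionIndexSeries(values=np.array([-1.0]), frame_rate=40.0)

    def test_frame_stack_loads_from_tiff_and_hdf5(self, rng, tmp_path):
        import h5py
        import tifffile
        from motorpop.signal_prep import load_frame_stack
        frames = rng.integers(0, 255, size=(4, 8, 8)).astype("uint8")
        tifffile.imwrite(tmp_path / "s.tif", frames)
        np.testing.assert_array_equal(load_frame_stack(tmp_path / "s.tif"), frames)
        with h5py.File(tmp_path / "s.h5", "w") as f:
            f.create_dataset("frames", data=frames)
        np.testing.assert_array_equal(load_frame_stack(tmp_path / "s.h5"), frames)


class TestLoess:
    def test_constant_unchanged(self):
        y = np.full(100, 3.7)
        np.testing.assert_allclose(loess_smooth(y, 1.0, 40.0), y, atol=1e-12)

    def test_linear_unchanged_including_boundaries(self):
        y = 0.5 * np.arange(200) - 3.0
        np.testing.assert_allclose(loess_smooth(y, 1.0, 40.0), y, atol=1e-9)

    def test_reduces_noise_around_sine(self, rng):
        t = np.arange(400) / 40.0
        clean = np.sin(2 * np.pi * 0.3 * t)
        worse = better = 0
        for _ in range(50):
            noisy = clean + rng.normal(0, 0.3, len(t))
            sm = loess_smooth(noisy, 1.0, 40.0)
            if np.var(sm - clean) < np.var(noisy - clean):
                better += 1
            else:
                worse += 1
        assert better > worse

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.zeros(50), 0.01, 40.0)


class TestDff:
    def test_constant_trace(self):
        traces = compute_dff(np.full((2, 800), 100.0), 40.0)
        np.testing.assert_allclose(traces.dff, 0.0, atol=1e-9)
        np.testing.assert_allclose(traces.f0, 100.0)

    def test_f0_is_fifth_percentile_of_lowpassed_trace(self):
        from scipy import signal as sps
        raw = np.full(4000, 100.0)
        for start in range(200, 3800, 400):
            raw[start:start + 20] = 200.0
        traces = compute_dff(raw[None, :], 40.0)
        # independent oracle: direct 5th percentile of the filtered signal
        sos = sps.butter(2, 1.0, btype="low", fs=40.0, output="sos")
        expected = np.percentile(sps.sosfiltfilt(sos, raw), 5)
        assert traces.f0[0] == pytest.approx(expected)
        # brief transients barely move the baseline (filter undershoot only)
        assert abs(traces.f0[0] - 100.0) / 100.0 < 0.05

    def test_scale_invariance(self, rng):
        raw = 100.0 + rng.random((3, 800)) * 10
        d1 = compute_dff(raw, 40.0).dff
        d2 = compute_dff(raw * 7.3, 40.0).dff
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_f0_monotone_in_pointwise_increase(self, rng):
        raw = 100.0 + rng.random((1, 800)) * 10
        bumped = raw + rng.random((1, 800))
        assert compute_dff(bumped, 40.0).f0[0] >= compute_dff(raw, 40.0).f0[0] - 1e-9

    def test_rejects_nonpositive_raw(self):
        with pytest.raises(ValueError, match="positive"):
            compute_dff(np.zeros((1, 800)), 40.0)


class TestMotionOnset:
    def _step_mi(self, t0_frame, n=800, fr=40.0):
        v = np.zeros(n)
        v[t0_frame:] = 1.0
        return MotionIndexSeries(v, fr)

    def test_noiseless_step_found_exactly(self):
        fr = 40.0
        mi = self._step_mi(400)
        onset = detect_motion_onset(mi, cue_s=9.0, movement_s=10.5, rng=np.random.default_rng(0))
        assert onset == pytest.approx(400 / fr)

    def test_below_threshold_returns_missing(self):
        mi = MotionIndexSeries(np.zeros(800), 40.0)
        onset = detect_motion_onset(mi, 9.0, 10.5, rng=np.random.default_rng(0))
        assert np.isnan(onset)

    def test_translation_equivariance(self):
        fr = 40.0
        v = np.zeros(1200)
        v[500:560] = np.linspace(0, 2, 60)
        shift = 80  # frames
        m1 = MotionIndexSeries(v, fr)
        m2 = MotionIndexSeries(np.roll(v, shift), fr)
        o1 = detect_motion_onset(m1, 10.0, 13.0, rng=np.random.default_rng(0))
        o2 = detect_motion_onset(m2, 10.0 + shift / fr, 13.0 + shift / fr,
                                 rng=np.random.default_rng(0))
        assert o2 == pytest.approx(o1 + shift / fr)

    def test_recovers_generator_initiation_times_without_noise(self):
        cfg = SynthConfig(n_neurons=2, n_push_trials=5, n_pull_trials=5,
                          noise_sd=0.0, onset_jitter_sd=0.0, seed=9)
        session, _ = generate_session(cfg)
        mi = MotionIndexSeries(session.motion_index, session.frame_rate)
        rng = np.random.default_rng(1)
        for row in session.trials.itertuples():
            onset = detect_motion_onset(mi, row.cue_s, row.motion_onset_s, rng=rng)
            assert abs(onset - row.motion_onset_s) <= 1.0 / session.frame_rate + 1e-9

    def test_ephys_mode_uses_mean_plus_2sd(self, rng):
        fr = 40.0
        v = rng.normal(1.0, 0.1, 1200)
        v = np.abs(v)
        v[500:] += 10.0
        mi = MotionIndexSeries(v, fr)
        onset = detect_motion_onset(mi, 11.0, 14.0, mode="ephys")
        assert onset == pytest.approx(500 / fr, abs=1 / fr)

    def test_out_of_range_baseline_rejected(self):
        mi = MotionIndexSeries(np.zeros(100), 40.0)
        with pytest.raises(ValueError):
            detect_motion_onset(mi, 0.5, 1.0)


class TestAlignTrials:
    def test_indexing_matches_raw_frames(self):
        traces = np.arange(400, dtype=float)[None, :]
        aligned = align_trials(traces, [100 / 40.0], (1.0, 1.0), 40.0, ["push"])
        assert aligned.data.shape == (1, 1, 81)
        assert aligned.data[0, 0, 40] == 100.0
        assert aligned.time_axis[40] == 0.0

    def test_identical_events_identical_slices(self, rng):
        traces = rng.random((2, 400))
        aligned = align_trials(traces, [5.0, 5.0], (1.0, 1.0), 40.0, ["push", "pull"])
        np.testing.assert_array_equal(aligned.data[:, 0], aligned.data[:, 1])

    def test_round_trip_copies(self, rng):
        traces = rng.random((1, 400))
        aligned = align_trials(traces, [5.0], (1.0, 1.0), 40.0, ["push"])
        lo = int(round(5.0 * 40)) - 40
        np.testing.assert_array_equal(aligned.data[0, 0], traces[0, lo:lo + 81])

    def test_out_of_range_trial_flagged_not_dropped(self, rng):
        traces = rng.random((1, 200))
        aligned = align_trials(traces, [0.1, 2.5], (1.0, 1.0), 40.0, ["push", "pull"])
        assert aligned.data.shape[1] == 2
        assert list(aligned.valid_trials) == [False, True]
        assert np.isnan(aligned.data[0, 0]).all()


class TestResample:
    def test_identity_grid(self, rng):
        tr = rng.random(50)
        np.testing.assert_allclose(resample_trials_fixed_length([tr], 50)[0], tr)

    def test_linear_preserved_with_endpoints(self):
        tr = np.linspace(2.0, 5.0, 37)
        out = resample_trials_fixed_length([tr], 80)[0]
        np.testing.assert_allclose(out, np.linspace(2.0, 5.0, 80), atol=1e-12)

    def test_down_up_roundtrip_error_bounded_by_curvature(self):
        t = np.linspace(0, 1, 400)
        tr = np.sin(2 * np.pi * t)
        down = resample_trials_fixed_length([tr], 50)[0]
        up = resample_trials_fixed_length([down], 400)[0]
        # linear-interp error bound: max second difference on the coarse grid
        h = 1 / 49
        bound = (2 * np.pi) ** 2 * h**2 / 8
        assert np.max(np.abs(up - tr)) < bound * 1.5

    def test_rejects_small_n_out(self):
        with pytest.raises(ValueError):
            resample_trials_fixed_length([np.arange(5.0)], 1)
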