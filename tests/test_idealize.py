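"""Idealization: histogram, level detection, thresholding, dead time."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkin.gating_sim import (
    AcquisitionConfig,
    StatePath,
    render_sweep,
    sample_path,
    simulate_recording,
    Sweep,
    preset_scheme,
    two_state_scheme,
)
from patchkin.idealize import (
    LevelSet,
    all_points_histogram,
    detect_levels,
    half_amplitude_thresholds,
    idealize,
    idealize_sweep,
)


def make_sweep(samples, fs=10_000.0):
    return Sweep(voltage=100.0, samples=np.asarray(samples, float),
                 sampling_rate=fs)


class TestAllPointsHistogram:
    def test_constant_trace_single_nonzero_bin(self):
        hist = all_points_histogram(make_sweep(np.full(1000, 5.0)), 0.1)
        nz = hist.counts[hist.counts > 0]
        assert len(nz) == 1 and nz[0] == 1000

    def test_two_level_trace_equal_counts(self):
        x = np.concatenate([np.zeros(500), np.full(500, 19.8)])
        hist = all_points_histogram(make_sweep(x), 0.1)
        nz = hist.counts[hist.counts > 0]
        assert list(nz) == [500, 500]

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5000)
        hist = all_points_histogram(make_sweep(x), 0.2)
        assert hist.counts.sum() == 5000

    def test_gaussian_mode_near_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.3, 200_000)
        hist = all_points_histogram(make_sweep(x), 0.05)
        mode = hist.bin_centers[np.argmax(hist.counts)]
        assert abs(mode - 2.0) <= 0.05

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            all_points_histogram(make_sweep([]), 0.1)


class TestDetectLevels:
    def test_noiseless_two_level(self):
        x = np.concatenate([np.zeros(500), np.full(500, 19.8)])
        hist = all_points_histogram(make_sweep(x), 0.1)
        levels = detect_levels(hist, min_separation=5.0)
        assert levels.n_levels == 1
        assert levels.baseline == pytest.approx(0.0, abs=0.1)
        assert levels.unitary_amplitude == pytest.approx(19.8, abs=0.2)

    def test_blocked_sweep_no_open_levels(self):
        scheme = preset_scheme("wt")
        cfg = AcquisitionConfig(sweep_duration=0.5, paxilline_block=True,
                                noise_sd=1.0, seed=3)
        rec = simulate_recording(scheme, cfg)
        sweep = rec.sweep_at(120.0)
        hist = all_points_histogram(sweep, 0.2)
        assert detect_levels(hist, min_separation=9.0).n_levels == 0

    def test_multichannel_amplitude_within_5pct(self):
        """3-channel patch at +140 mV: >= 2 levels, spacing ~ gamma*V."""
        scheme = two_state_scheme(300.0, 300.0)
        cfg = AcquisitionConfig(sweep_duration=2.0, n_channels=3,
                                protocol_voltages=(140.0,), noise_sd=1.0,
                                seed=9)
        rec = simulate_recording(scheme, cfg)
        expected = cfg.unitary_current(140.0)
        _, levels = idealize(rec.sweeps[0], expected_unitary=expected,
                             filter_cutoff=cfg.filter_cutoff)
        assert levels.n_levels >= 2
        assert abs(levels.unitary_amplitude / expected - 1) < 0.05


class TestThresholds:
    def test_midpoint_single_level(self):
        ls = LevelSet(baseline=0.0, unitary_amplitude=20.0, n_levels=1)
        assert half_amplitude_thresholds(ls) == [10.0]

    def test_multi_level_spacing(self):
        ls = LevelSet(baseline=1.0, unitary_amplitude=20.0, n_levels=3)
        assert half_amplitude_thresholds(ls) == [11.0, 31.0, 51.0]

    def test_no_levels_empty(self):
        ls = LevelSet(baseline=0.0, unitary_amplitude=0.0, n_levels=0)
        assert half_amplitude_thresholds(ls) == []


class TestIdealizeSweep:
    def test_all_below_threshold_single_event(self):
        ev = idealize_sweep(make_sweep(np.zeros(1000)), [5.0])
        assert len(ev) == 1
        assert ev.levels[0] == 0
        assert ev.durations[0] == pytest.approx(0.1)

    def test_square_wave_alternating_events(self):
        fs = 10_000.0
        period = int(fs * 0.01)  # 10 ms
        x = np.tile(np.concatenate([np.zeros(period), np.full(period, 20.0)]), 5)
        ev = idealize_sweep(make_sweep(x, fs), [10.0])
        assert len(ev) == 10
        assert np.all(ev.levels == np.tile([0, 1], 5))
        assert np.allclose(ev.durations, 0.01)

    def test_empty_thresholds_all_closed(self):
        ev = idealize_sweep(make_sweep(np.full(500, 3.0)), [])
        assert len(ev) == 1 and ev.levels[0] == 0

    def test_dead_time_merges_brief_events(self):
        fs = 10_000.0
        x = np.zeros(1000)
        x[500] = 20.0  # one-sample blip
        ev = idealize_sweep(make_sweep(x, fs), [10.0], dead_time=0.0005)
        assert len(ev) == 1 and ev.levels[0] == 0

    def test_duration_conservation_with_dead_time(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 3, 4000)
        ev = idealize_sweep(make_sweep(x), [2.0], dead_time=0.001)
        assert ev.durations.sum() == pytest.approx(0.4, abs=1e-4)

    def test_noisy_single_channel_open_time_within_5pct(self):
        """SNR >= 8: recovered total open time tracks the ground truth."""
        scheme = two_state_scheme(100.0, 100.0)
        cfg = AcquisitionConfig(sweep_duration=5.0, protocol_voltages=(120.0,),
                                noise_sd=1.0, unitary_conductance=165.0, seed=12)
        rec = simulate_recording(scheme, cfg)
        sweep = rec.sweeps[0]
        truth_open = sweep.truth_paths[0].open_fraction(scheme) * 5.0
        ev, _ = idealize(sweep, expected_unitary=cfg.unitary_current(120.0),
                         filter_cutoff=cfg.filter_cutoff)
        assert abs(ev.time_at_level(1) / truth_open - 1) < 0.05


class TestRoundTrip:
    def test_zero_noise_round_trip_event_exact(self):
        """Noiseless unfiltered rendering idealizes back to the truth path."""
        slow = two_state_scheme(20.0, 20.0)
        cfg = AcquisitionConfig(sweep_duration=5.0, noise_sd=0.0,
                                filter_cutoff=None, protocol_voltages=(120.0,),
                                seed=21)
        path = sample_path(slow, 120.0, 5.0, seed=21)
        sweep = render_sweep([path], slow, 120.0, cfg)
        ev, _ = idealize(sweep, expected_unitary=cfg.unitary_current(120.0),
                         dead_time_s=0.0)
        truth_levels = [1 if s == "O" else 0 for s in path.states]
        assert list(ev.levels) == truth_levels
        # each boundary within one sample period
        truth_starts = np.concatenate([[0.0], np.cumsum(path.dwells)[:-1]])
        assert np.max(np.abs(ev.starts - truth_starts)) <= 1.0 / cfg.sampling_rate

    def test_per_sample_round_trip_is_exact(self, two_state):
        cfg = AcquisitionConfig(sweep_duration=2.0, noise_sd=0.0,
                                filter_cutoff=None, protocol_voltages=(100.0,),
                                seed=8)
        path = sample_path(two_state, 100.0, 2.0, seed=8)
        sweep = render_sweep([path], two_state, 100.0, cfg)
        ev, _ = idealize(sweep, expected_unitary=cfg.unitary_current(100.0),
                         dead_time_s=0.0)
        truth = path.occupancy(two_state, sweep.times)
        recon = np.repeat(
            ev.levels, np.round(ev.durations * cfg.sampling_rate).astype(int)
        )
        np.testing.assert_array_equal(recon, truth)


class TestProperties:
    @given(
        seed=st.integers(0, 10_000),
        thr=st.floats(0.5, 15.0),
        shift=st.floats(0.1, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_raising_thresholds_never_increases_open_time(self, seed, thr, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(5.0, 4.0, 2000)
        lo = idealize_sweep(make_sweep(x), [thr])
        hi = idealize_sweep(make_sweep(x), [thr + shift])
        assert hi.time_at_level(1) <= lo.time_at_level(1) + 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_event_durations_cover_sweep(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 2.0, 1500)
        ev = idealize_sweep(make_sweep(x), [1.0, 3.0], dead_time=0.0008)
        assert ev.durations.sum() == pytest.approx(0.15, abs=1e-4)
        assert np.all(np.diff(ev.levels) != 0)

    @given(seed=st.integers(0, 10_000), thr=st.floats(-2.0, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_event_occupancy_equals_per_sample_oracle(self, seed, thr):
        rng = np.random.default_rng(seed)
        x = rng.normal(3.0, 3.0, 1000)
        ev = idealize_sweep(make_sweep(x), [thr])
        oracle_open = np.sum(x > thr) / 10_000.0
        assert ev.time_at_level(1) == pytest.approx(oracle_open, abs=1e-9)
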