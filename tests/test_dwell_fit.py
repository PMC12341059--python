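"""Dwell collection, log binning, and time-constant fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkin.dwell_fit import (
    DwellSample,
    collect_dwells,
    fit_closed,
    fit_open,
    log_bin,
)
from patchkin.gating_sim import (
    AcquisitionConfig,
    mean_dwell,
    render_sweep,
    sample_path,
    wt_like_scheme,
)
from patchkin.idealize import idealize
from helpers import events_from


class TestCollectDwells:
    def test_square_wave_dwells(self):
        levels = [0, 1] * 750
        ev = events_from(levels, [0.01] * 1500)
        open_sample = collect_dwells(ev, "open")
        assert len(open_sample) == pytest.approx(749, abs=1)
        assert np.allclose(open_sample.durations, 0.01)

    def test_all_closed_gives_empty_open_sample(self):
        ev = events_from([0, 1, 0], [5.0, 0.01, 5.0])
        # interior events only: one open dwell, zero closed dwells
        assert len(collect_dwells(ev, "closed")) == 0
        assert len(collect_dwells(ev, "open")) == 1

    def test_multilevel_rejected(self):
        ev = events_from([0, 2, 0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="single-channel"):
            collect_dwells(ev, "open")

    def test_zero_noise_closed_dwells_match_truth(self):
        """Rendered C2-C1-O path returns its closed sojourns exactly."""
        scheme = wt_like_scheme()
        cfg = AcquisitionConfig(sweep_duration=3.0, noise_sd=0.0,
                                filter_cutoff=None, protocol_voltages=(140.0,),
                                seed=5)
        path = sample_path(scheme, 140.0, 3.0, seed=5)
        sweep = render_sweep([path], scheme, 140.0, cfg)
        ev, _ = idealize(sweep, expected_unitary=cfg.unitary_current(140.0),
                         dead_time_s=0.0)
        got = collect_dwells(ev, "closed").durations
        # oracle: discretize the truth path at the sampling grid (sojourns
        # shorter than one sample are invisible by construction), then
        # run-length encode and take the interior closed runs
        dt = 1.0 / cfg.sampling_rate
        occ = path.occupancy(scheme, sweep.times)
        change = np.flatnonzero(np.diff(occ)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [occ.size]])
        runs = [(occ[a], (b - a) * dt) for a, b in zip(starts, ends)]
        truth = np.array([d for lv, d in runs[1:-1] if lv == 0])
        assert len(got) == len(truth)
        np.testing.assert_allclose(np.sort(got), np.sort(truth), atol=1e-12)


class TestLogBin:
    def test_identical_dwells_single_bin(self):
        h = log_bin(DwellSample("open", np.full(100, 1e-3)), 10)
        nz = np.flatnonzero(h.counts)
        assert len(nz) == 1
        assert abs(h.log10_centers[nz[0]] - (-3.0)) <= 0.1

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(5e-3, 4321)
        h = log_bin(DwellSample("closed", d), 10)
        assert h.counts.sum() == 4321

    def test_exponential_argmax_at_tau(self):
        """Peak-at-tau: the mode of the log-binned histogram sits at tau."""
        rng = np.random.default_rng(7)
        d = rng.exponential(10e-3, 100_000)
        h = log_bin(DwellSample("open", d), 10)
        peak = h.log10_centers[np.argmax(h.counts)]
        assert abs(peak - np.log10(10e-3)) <= 0.1

    def test_mixture_shows_two_maxima(self):
        rng = np.random.default_rng(8)
        n = 100_000
        comp = rng.random(n) < 0.5
        d = np.where(comp, rng.exponential(1e-4, n), rng.exponential(0.1, n))
        h = log_bin(DwellSample("closed", d), 10)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(h.counts.astype(float),
                              prominence=0.2 * h.counts.max())
        assert len(peaks) >= 2
        locs = h.log10_centers[peaks]
        assert np.min(np.abs(locs - (-4))) < 0.2
        assert np.min(np.abs(locs - (-1))) < 0.2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            log_bin(DwellSample("open", np.array([])), 10)


class TestFitOpen:
    def test_recovers_exponential_tau_within_5pct(self):
        rng = np.random.default_rng(11)
        d = rng.exponential(5e-3, 10_000)
        fit = fit_open(log_bin(DwellSample("open", d), 10))
        assert fit.converged
        assert abs(fit.taus[0] / 5e-3 - 1) < 0.05

    def test_single_spike_degenerate_histogram(self):
        fit = fit_open(log_bin(DwellSample("open", np.full(100, 2e-3)), 10))
        assert fit.converged
        assert abs(np.log10(fit.taus[0]) - np.log10(2e-3)) <= 0.1

    def test_simulated_open_dwells_match_scheme_mean(self):
        """tau_open from a rendered patch tracks the analytic mean dwell."""
        scheme = wt_like_scheme()
        target = mean_dwell(scheme, "O", 140.0)
        path = sample_path(scheme, 140.0, 40.0, seed=19)
        d = np.array([dw for s, dw in zip(path.states[1:-1], path.dwells[1:-1])
                      if s == "O"])
        assert len(d) > 500
        fit = fit_open(log_bin(DwellSample("open", d), 10))
        assert abs(fit.taus[0] / target - 1) < 0.10

    def test_small_sample_warns(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(1e-3, 20)
        with pytest.warns(UserWarning, match="recommended"):
            fit = fit_open(log_bin(DwellSample("open", d), 10))
        assert fit.warning is not None


class TestFitClosed:
    def test_recovers_published_mixture_within_10pct(self):
        """Equal-weight mixture with fast/slow constants 0.049 ms / 9.1 ms."""
        rng = np.random.default_rng(23)
        n = 10_000
        comp = rng.random(n) < 0.5
        d = np.where(comp, rng.exponential(4.9e-5, n), rng.exponential(9.1e-3, n))
        fit = fit_closed(log_bin(DwellSample("closed", d), 10))
        assert fit.converged and not fit.effectively_single
        assert abs(fit.taus[0] / 4.9e-5 - 1) < 0.10
        assert abs(fit.taus[1] / 9.1e-3 - 1) < 0.10
        assert fit.weights[0] == pytest.approx(0.5, abs=0.1)

    def test_pure_exponential_flagged_single(self):
        rng = np.random.default_rng(29)
        d = rng.exponential(2e-3, 10_000)
        fit = fit_closed(log_bin(DwellSample("closed", d), 10))
        assert fit.converged
        assert fit.effectively_single or abs(
            np.log(fit.taus[1] / fit.taus[0])
        ) < 0.7

    def test_taus_strictly_increasing_weights_normalized(self):
        rng = np.random.default_rng(31)
        n = 5_000
        comp = rng.random(n) < 0.3
        d = np.where(comp, rng.exponential(1e-4, n), rng.exponential(2e-2, n))
        fit = fit_closed(log_bin(DwellSample("closed", d), 10))
        assert fit.taus[0] < fit.taus[1]
        assert sum(fit.weights) == pytest.approx(1.0)

    def test_closed_spectrum_matches_subgenerator_eigenvalues(self):
        """Fitted closed constants track the closed-class eigenvalue spectrum."""
        scheme = wt_like_scheme()
        v = 140.0
        labels = ["C2", "C1"]
        q = scheme.generator(v)
        idx = [scheme.state_labels.index(s) for s in labels]
        qcc = q[np.ix_(idx, idx)]
        eig = np.sort(-np.linalg.eigvals(qcc).real)  # 1/tau, ascending
        taus_true = np.sort(1.0 / eig)  # fast, slow after sorting taus
        path = sample_path(scheme, v, 120.0, seed=37)
        merged, cur = [], None
        for s, dw in zip(path.states[1:-1], path.dwells[1:-1]):
            if s != "O":
                cur = dw if cur is None else cur + dw
            elif cur is not None:
                merged.append(cur)
                cur = None
        fit = fit_closed(log_bin(DwellSample("closed", np.array(merged)), 10))
        assert abs(fit.taus[0] / taus_true[0] - 1) < 0.15
        assert abs(fit.taus[1] / taus_true[1] - 1) < 0.15


class TestFitProperties:
    @given(scale=st.floats(0.2, 50.0))
    @settings(max_examples=10, deadline=None)
    def test_scale_equivariance(self, scale):
        """Multiplying dwells by c multiplies the fitted tau by c."""
        rng = np.random.default_rng(41)
        d = rng.exponential(3e-3, 5_000)
        base = fit_open(log_bin(DwellSample("open", d), 10)).taus[0]
        scaled = fit_open(log_bin(DwellSample("open", d * scale), 10)).taus[0]
        assert abs(scaled / (base * scale) - 1) < 0.05

    def test_rmse_decreases_with_sample_size(self):
        tau = 5e-3
        rmses = []
        for n in (100, 10_000):
            errs = []
            for seed in range(12):
                rng = np.random.default_rng(1000 + seed)
                d = rng.exponential(tau, n)
                fit = fit_open(log_bin(DwellSample("open", d), 10))
                errs.append(fit.taus[0] / tau - 1)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[1] < rmses[0]
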