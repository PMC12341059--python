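"""Half-amplitude threshold idealization of sampled current sweeps.

The pipeline follows standard single-channel practice: build an
all-points amplitude histogram, locate the closed and open current
peaks, place event-detection thresholds midway between adjacent levels
(50% threshold analysis), and compress the per-sample level sequence
into contiguous dwell events, merging events briefer than the filter
dead time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .gating_sim import Sweep

__all__ = [
    "AllPointsHistogram",
    "LevelSet",
    "EventList",
    "all_points_histogram",
    "detect_levels",
    "half_amplitude_thresholds",
    "idealize_sweep",
    "idealize",
    "dead_time",
]


@dataclass(frozen=True)
class AllPointsHistogram:
    """Amplitude histogram over every sample of a sweep."""

    bin_edges: np.ndarray  # pA, len = n_bins + 1
    counts: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("histogram does not conserve sample count")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class LevelSet:
    """Detected current levels: closed baseline plus open multiples."""

    baseline: float  # pA
    unitary_amplitude: float  # pA between adjacent levels
    n_levels: int  # open levels detected (0 = all-closed patch)
    # False when the amplitude was assumed from the nominal conductance
    # (pinned-open sweep with a single histogram peak), not measured
    amplitude_measured: bool = True

    def __post_init__(self) -> None:
        if self.n_levels > 0 and self.unitary_amplitude <= 0:
            raise ValueError("unitary_amplitude must be positive")
        if self.n_levels < 0:
            raise ValueError("n_levels must be >= 0")


@dataclass(frozen=True)
class EventList:
    """Idealized sweep: contiguous (level, start, duration) events."""

    levels: np.ndarray  # int occupancy level per event
    starts: np.ndarray  # s
    durations: np.ndarray  # s
    sweep_duration: float
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.starts) == len(self.durations)):
            raise ValueError("ragged event arrays")
        if len(self.levels) == 0:
            raise ValueError("event list must cover the sweep")
        if np.any(self.durations <= 0):
            raise ValueError("event durations must be positive")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def max_level(self) -> int:
        return int(self.levels.max())

    def time_at_level(self, level: int) -> float:
        return float(self.durations[self.levels == level].sum())


def all_points_histogram(sweep: Sweep, bin_width: float) -> AllPointsHistogram:
    """Histogram of every sample amplitude at fixed ``bin_width`` (pA)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(sweep.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sweep")
    # one empty guard bin below and above the data so no amplitude peak
    # is a boundary maximum (local-maximum search would miss it)
    lo = (np.floor(x.min() / bin_width) - 1.0) * bin_width
    n_bins = max(1, int(np.ceil((x.max() - lo) / bin_width)) + 2)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return AllPointsHistogram(bin_edges=edges, counts=counts, n_samples=x.size)


def estimate_noise_sd(sweep: Sweep) -> float:
    """Robust within-level noise sd from successive sample differences.

    Differencing cancels the (piecewise-constant) level structure except
    at the rare transition samples, which the median absolute deviation
    ignores. Low-pass filtering correlates neighbouring samples, so this
    under-reads the total sd somewhat; it is used only to scale the
    histogram bin width.
    """
    x = np.asarray(sweep.samples, dtype=float)
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def default_bin_width(sweep: Sweep) -> float:
    """Half the baseline noise sd, floored at 0.05 pA."""
    return max(0.05, estimate_noise_sd(sweep) / 2.0)


def detect_levels(
    hist: AllPointsHistogram,
    min_separation: float,
    prominence_frac: float = 0.05,
    baseline_hint: float | None = None,
    expected_unitary: float | None = None,
) -> LevelSet:
    """Locate amplitude peaks; lowest peak is the closed baseline.

    Peaks are local maxima of the all-points histogram with prominence
    at least ``prominence_frac`` of the tallest peak and mutual
    separation at least ``min_separation`` pA. The unitary amplitude is
    the median spacing of consecutive peaks (levels are assumed equally
    spaced).

    When ``baseline_hint`` (the known closed-level current, e.g. 0 pA
    for a leak-free cell-attached sweep) is given, the level lattice is
    anchored there: a lowest peak sitting well above the hint is read
    as an already-open level rather than as baseline, which otherwise
    misassigns sweeps recorded at near-saturating open probability.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    distance = max(1, int(round(min_separation / hist.bin_width)))
    prominence = prominence_frac * counts.max()
    peaks, _ = _signal.find_peaks(
        counts, prominence=prominence, distance=distance
    )
    if len(peaks) == 0:
        # a single boundary maximum (e.g. one constant level) has no
        # interior local maximum; fall back to the global mode
        peaks = np.array([int(np.argmax(counts))])
    # refine each peak position by the count-weighted centroid of the
    # bins within half the level separation, removing bin quantization
    half = max(1, int(round(0.5 * min_separation / hist.bin_width)) - 1)
    all_centers = hist.bin_centers
    centers = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(counts), p + half + 1)
        w = counts[lo:hi]
        centers.append(float(np.average(all_centers[lo:hi], weights=w)))
    centers = np.asarray(centers)
    if len(centers) == 1:
        c0 = float(centers[0])
        if baseline_hint is not None and expected_unitary:
            k0 = int(round((c0 - baseline_hint) / expected_unitary))
            if k0 >= 1:  # patch pinned open: the sole peak is a level
                return LevelSet(
                    baseline=c0 - k0 * expected_unitary,
                    unitary_amplitude=float(expected_unitary),
                    n_levels=k0,
                    amplitude_measured=False,
                )
        return LevelSet(baseline=c0, unitary_amplitude=0.0, n_levels=0)
    unitary = float(np.median(np.diff(centers)))
    k0 = 0
    if baseline_hint is not None:
        k0 = max(0, int(round((centers[0] - baseline_hint) / unitary)))
    return LevelSet(
        baseline=float(centers[0]) - k0 * unitary,
        unitary_amplitude=unitary,
        n_levels=k0 + len(centers) - 1,
    )


def half_amplitude_thresholds(levels: LevelSet) -> list[float]:
    """50% thresholds: baseline + (k - 1/2) x unitary amplitude."""
    return [
        levels.baseline + (k - 0.5) * levels.unitary_amplitude
        for k in range(1, levels.n_levels + 1)
    ]


def dead_time(filter_cutoff: float | None) -> float:
    """Rise-time dead time T_d = 0.179 / f_c for a Gaussian-type filter."""
    if filter_cutoff is None or filter_cutoff <= 0:
        return 0.0
    return 0.179 / filter_cutoff


def _merge_short_events(
    levels: list[int], durations: list[float], td: float
) -> tuple[list[int], list[float]]:
    """Merge events shorter than ``td`` into the longer adjacent event.

    First and last events are boundary-truncated and exempt. Shortest
    events are resolved first; merging re-joins same-level neighbours.
    """

    def coalesce(lv: list[int], du: list[float]):
        out_l, out_d = [lv[0]], [du[0]]
        for l, d in zip(lv[1:], du[1:]):
            if l == out_l[-1]:
                out_d[-1] += d
            else:
                out_l.append(l)
                out_d.append(d)
        return out_l, out_d

    levels, durations = coalesce(levels, durations)
    while len(levels) > 2:
        interior = np.asarray(durations[1:-1])
        short = np.flatnonzero(interior < td)
        if short.size == 0:
            break
        i = 1 + int(short[np.argmin(interior[short])])
        left_d = durations[i - 1]
        right_d = durations[i + 1]
        target = i - 1 if left_d >= right_d else i + 1
        levels[i] = levels[target]
        levels, durations = coalesce(levels, durations)
    return levels, durations


def idealize_sweep(
    sweep: Sweep,
    thresholds: list[float],
    dead_time: float = 0.0,
) -> EventList:
    """Classify samples against thresholds and compress into events.

    A sample's level is the number of thresholds strictly below it.
    Events briefer than ``dead_time`` (other than the boundary events)
    are merged into the longer neighbouring event.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    thr = np.asarray(thresholds, dtype=float)
    if thr.size and np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    x = np.asarray(sweep.samples, dtype=float)
    dt = 1.0 / sweep.sampling_rate
    if thr.size == 0:
        sample_levels = np.zeros(x.size, dtype=int)
    else:
        sample_levels = np.searchsorted(thr, x, side="left").astype(int)
    # run-length encode
    change = np.flatnonzero(np.diff(sample_levels)) + 1
    starts_idx = np.concatenate([[0], change])
    ends_idx = np.concatenate([change, [x.size]])
    levels = sample_levels[starts_idx].tolist()
    durations = ((ends_idx - starts_idx) * dt).tolist()
    if dead_time > 0 and len(levels) > 2:
        levels, durations = _merge_short_events(levels, durations, dead_time)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return EventList(
        levels=np.asarray(levels, dtype=int),
        starts=starts,
        durations=np.asarray(durations, dtype=float),
        sweep_duration=x.size * dt,
        dead_time=dead_time,
    )


def idealize(
    sweep: Sweep,
    expected_unitary: float | None = None,
    bin_width: float | None = None,
    dead_time_s: float | None = None,
    filter_cutoff: float | None = None,
    prominence_frac: float = 0.05,
    baseline_hint: float | None = None,
) -> tuple[EventList, LevelSet]:
    """Full idealization of one sweep: histogram -> levels -> events.

    ``expected_unitary`` (pA) sets the peak-separation floor to half the
    expected level spacing; when omitted it is guessed from the sample
    range. Sweeps with negative driving force should be sign-flipped by
    the caller (see pipeline) so that open levels lie above baseline.
    """
    bw = bin_width if bin_width is not None else default_bin_width(sweep)
    hist = all_points_histogram(sweep, bw)
    if expected_unitary is None:
        span = float(np.ptp(sweep.samples))
        expected_unitary = max(span / 6.0, 4 * bw)
    levels = detect_levels(
        hist,
        min_separation=0.5 * abs(expected_unitary),
        prominence_frac=prominence_frac,
        baseline_hint=baseline_hint,
        expected_unitary=abs(expected_unitary),
    )
    thr = half_amplitude_thresholds(levels)
    td = dead_time_s if dead_time_s is not None else dead_time(filter_cutoff)
    events = idealize_sweep(sweep, thr, dead_time=td)
    return events, levels
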