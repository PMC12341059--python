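"""Log-binned dwell-time histograms and time-constant fitting.

Dwell durations at one level are histogrammed with bins of constant
width in log time. In that coordinate an exponential component of time
constant tau appears as a fixed-shape peak located exactly at tau, so
the transform turns time-constant estimation into peak fitting: open
dwells are fitted with one component (tau_open) and closed dwells with
two (tau_closed1 fast, tau_closed2 slow).

The component is the log-transformed exponential density

    g(x) = A * exp((x - x_tau) - exp(x - x_tau)),   x = ln t,

whose maximum sits at x_tau = ln tau; A integrates (over ln t) to the
component's event count. A literal log-normal peak is available as an
option but does not have the peak-at-tau property.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .idealize import EventList

__all__ = [
    "DwellSample",
    "LogHistogram",
    "DwellFitResult",
    "collect_dwells",
    "log_bin",
    "fit_open",
    "fit_closed",
]

MIN_DWELLS_RECOMMENDED = 50
LN10 = math.log(10.0)


@dataclass(frozen=True)
class DwellSample:
    """Dwell durations of one kind from a single-channel patch."""

    kind: str  # "open" | "closed"
    durations: np.ndarray  # s
    source_patch: str = ""
    voltage: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("open", "closed"):
            raise ValueError("kind must be 'open' or 'closed'")
        if np.any(np.asarray(self.durations) <= 0):
            raise ValueError("dwell durations must be positive")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class LogHistogram:
    """Histogram with constant-width bins on a log10 time axis."""

    log10_edges: np.ndarray
    counts: np.ndarray
    bins_per_decade: int

    def __post_init__(self) -> None:
        widths = np.diff(self.log10_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have constant log-width")

    @property
    def log10_centers(self) -> np.ndarray:
        return 0.5 * (self.log10_edges[:-1] + self.log10_edges[1:])

    @property
    def centers_s(self) -> np.ndarray:
        return 10.0 ** self.log10_centers

    @property
    def ln_bin_width(self) -> float:
        return float(np.diff(self.log10_edges)[0]) * LN10


@dataclass(frozen=True)
class DwellFitResult:
    """Fitted peak-at-tau components for one dwell histogram."""

    components: tuple[tuple[float, float], ...]  # (tau_s, weight)
    kind: str
    sse: float
    converged: bool
    effectively_single: bool = False
    warning: str | None = None

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.components)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.components)


def collect_dwells(
    events: EventList,
    kind: str,
    source_patch: str = "",
    voltage: float = float("nan"),
) -> DwellSample:
    """Extract open (level 1) or closed (level 0) dwells from one sweep.

    Only single-channel event lists (levels 0/1) are accepted; the first
    and last events are boundary-truncated and excluded.
    """
    if events.max_level > 1:
        raise ValueError(
            "dwell analysis requires a single-channel patch (levels 0/1); "
            "this event list reaches level "
            f"{events.max_level} — select single-channel patches"
        )
    want = 1 if kind == "open" else 0
    lv = events.levels[1:-1]
    du = events.durations[1:-1]
    return DwellSample(
        kind=kind,
        durations=np.asarray(du[lv == want], dtype=float),
        source_patch=source_patch,
        voltage=voltage,
    )


def log_bin(dwells: DwellSample, bins_per_decade: int = 10) -> LogHistogram:
    """Bin dwells at constant width in log10 time, padded one bin per side."""
    if bins_per_decade < 5:
        raise ValueError("bins_per_decade must be >= 5")
    d = np.asarray(dwells.durations, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell sample")
    w = 1.0 / bins_per_decade
    lo = (np.floor(np.log10(d.min()) / w) - 1.0) * w
    hi = (np.ceil(np.log10(d.max()) / w) + 1.0) * w
    n_bins = int(round((hi - lo) / w))
    edges = lo + w * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.log10(d), bins=edges)
    return LogHistogram(
        log10_edges=edges, counts=counts, bins_per_decade=bins_per_decade
    )


def _peak_component(x: np.ndarray, amp: float, x_tau: float) -> np.ndarray:
    y = x - x_tau
    return amp * np.exp(y - np.exp(y))


def _lognormal_component(
    x: np.ndarray, amp: float, x_tau: float, sigma: float = 1.0
) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - x_tau) / sigma) ** 2)


def _prominent_maxima(counts: np.ndarray, k: int) -> list[int]:
    """Indices of up to k most prominent local maxima, ties toward small tau."""
    from scipy.signal import find_peaks

    peaks, props = find_peaks(counts, prominence=0.0)
    if len(peaks) == 0:
        return [int(np.argmax(counts))]
    order = np.argsort(-props["prominences"], kind="stable")
    chosen = sorted(peaks[order][:k].tolist())
    return chosen


def _fit(
    hist: LogHistogram,
    n_components: int,
    kind: str,
    n_dwells: int | None,
    component: str,
) -> DwellFitResult:
    counts = np.asarray(hist.counts, dtype=float)
    x = hist.log10_centers * LN10  # work in natural-log time
    nonzero = np.flatnonzero(counts)
    warning = None
    if n_dwells is not None and n_dwells < MIN_DWELLS_RECOMMENDED:
        warning = (
            f"only {n_dwells} dwells; at least {MIN_DWELLS_RECOMMENDED} "
            "recommended for a stable fit"
        )
        warnings.warn(warning, stacklevel=3)
    if nonzero.size == 1:
        # degenerate single-bin histogram: the peak position IS the bin
        tau = float(np.exp(x[nonzero[0]]))
        comps = tuple((tau, 1.0) for _ in range(1))
        return DwellFitResult(
            components=comps,
            kind=kind,
            sse=0.0,
            converged=True,
            effectively_single=n_components > 1,
            warning=warning,
        )

    shape = _peak_component if component == "peak_at_tau" else _lognormal_component
    init_idx = _prominent_maxima(counts, n_components)
    while len(init_idx) < n_components:
        # fall back: spread additional starts across the occupied range
        init_idx.append(int(nonzero[-1]))
    # amplitude of g at its max is A/e
    params = lmfit.Parameters()
    x_lo, x_hi = x[0] - LN10, x[-1] + LN10
    for j in range(n_components):
        amp0 = max(counts[init_idx[j]] * math.e, 1.0)
        params.add(f"amp{j}", value=amp0, min=0.0)
        if j == 0:
            params.add(f"xt{j}", value=x[init_idx[j]], min=x_lo, max=x_hi)
        else:
            # strictly increasing taus via positive log-spacing
            d0 = max(x[init_idx[j]] - x[init_idx[j - 1]], 0.5 * LN10)
            params.add(f"dx{j}", value=d0, min=1e-6, max=x_hi - x_lo)

    def model(p) -> np.ndarray:
        total = np.zeros_like(x)
        xt = p["xt0"].value
        for j in range(n_components):
            if j > 0:
                xt = xt + p[f"dx{j}"].value
            total = total + shape(x, p[f"amp{j}"].value, xt)
        return total

    def resid(p):
        return model(p) - counts

    out = lmfit.minimize(resid, params, method="leastsq")
    converged = bool(out.success)
    p = out.params
    xts, amps = [], []
    xt = p["xt0"].value
    for j in range(n_components):
        if j > 0:
            xt = xt + p[f"dx{j}"].value
        xts.append(xt)
        amps.append(p[f"amp{j}"].value)
    amps = np.asarray(amps, dtype=float)
    total_amp = amps.sum()
    if not converged or total_amp <= 0:
        return DwellFitResult(
            components=(), kind=kind, sse=float(np.sum(resid(p) ** 2)),
            converged=False, warning=warning,
        )
    weights = amps / total_amp
    comps = tuple(
        (float(np.exp(xt_)), float(w_)) for xt_, w_ in zip(xts, weights)
    )
    # second component vanishing or collapsing onto the first
    eff_single = n_components > 1 and (
        min(weights) < 0.01 or (xts[-1] - xts[0]) < 0.05
    )
    return DwellFitResult(
        components=comps,
        kind=kind,
        sse=float(np.sum(resid(p) ** 2)),
        converged=True,
        effectively_single=eff_single,
        warning=warning,
    )


def fit_open(
    hist: LogHistogram,
    n_dwells: int | None = None,
    component: str = "peak_at_tau",
) -> DwellFitResult:
    """Single-component fit of an open-dwell histogram (tau_open)."""
    if n_dwells is None:
        n_dwells = int(hist.counts.sum())
    return _fit(hist, 1, "open", n_dwells, component)


def fit_closed(
    hist: LogHistogram,
    n_dwells: int | None = None,
    component: str = "peak_at_tau",
) -> DwellFitResult:
    """Two-component fit of a closed-dwell histogram (tau_closed1 < tau_closed2)."""
    if n_dwells is None:
        n_dwells = int(hist.counts.sum())
    return _fit(hist, 2, "closed", n_dwells, component)
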