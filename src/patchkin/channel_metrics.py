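"""Per-patch ensemble and single-channel statistics.

NPo (expected number of simultaneously open channels), channel count N,
Po = NPo/N, unitary current-voltage points and the ohmic slope
conductance fitted over a stated voltage window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .idealize import EventList, LevelSet

__all__ = [
    "SweepMetrics",
    "PatchSummary",
    "IVPoint",
    "ConductanceFit",
    "npo",
    "estimate_n",
    "po_from_npo",
    "unitary_current",
    "slope_conductance",
]


@dataclass(frozen=True)
class SweepMetrics:
    """NPo and per-level occupancy times for one sweep."""

    voltage: float  # mV
    NPo: float
    time_at_level: dict[int, float]  # level -> s
    total_time: float  # s


@dataclass(frozen=True)
class PatchSummary:
    """Per-patch channel count and NPo/Po tables."""

    patch_id: str
    n_channels: int
    npo_by_voltage: dict[float, float]
    po_by_voltage: dict[float, float]

    @property
    def is_single_channel(self) -> bool:
        return self.n_channels == 1


@dataclass(frozen=True)
class IVPoint:
    voltage: float  # mV
    unitary_current: float  # pA, signed with driving force


@dataclass(frozen=True)
class ConductanceFit:
    slope_conductance: float  # pS
    intercept: float  # pA
    r_squared: float
    n_points: int


def npo(events: EventList, voltage: float = float("nan")) -> SweepMetrics:
    """NPo = sum_k k * t_k / T over the idealized sweep.

    Equivalent to the time-averaged occupancy level; for a single
    channel it reduces to the open fraction O/(O+C).
    """
    total = float(events.durations.sum())
    if total <= 0:
        raise ValueError("zero-duration sweep")
    t_at = {}
    for level in np.unique(events.levels):
        t_at[int(level)] = float(events.durations[events.levels == level].sum())
    value = sum(k * t for k, t in t_at.items()) / total
    return SweepMetrics(
        voltage=voltage, NPo=value, time_at_level=t_at, total_time=total
    )


def estimate_n(
    events_by_voltage: dict[float, EventList], top_k: int = 2
) -> int:
    """Channel count N: maximum simultaneous open level at high voltage.

    Only the highest ``top_k`` protocol voltages are consulted (where Po
    is maximal and the chance of never seeing all channels open together
    is smallest). Known to undercount at low Po.
    """
    if not events_by_voltage:
        raise ValueError("no idealized sweeps")
    top = sorted(events_by_voltage)[-top_k:]
    return int(max(events_by_voltage[v].max_level for v in top))


def po_from_npo(metrics: SweepMetrics, n: int) -> float:
    """Average single-channel open probability Po = NPo / N, in [0, 1]."""
    if n < 1:
        raise ValueError("channel count must be >= 1 to compute Po")
    return float(np.clip(metrics.NPo / n, 0.0, 1.0))


def unitary_current(levels: LevelSet, voltage: float) -> IVPoint | None:
    """I-V point from a sweep's level set; None when unresolvable.

    At small driving force no open level separates from baseline and the
    operation emits nothing rather than imputing a value; likewise when
    the level spacing was assumed rather than measured (pinned-open
    sweep). The caller is responsible for sign: ``levels`` comes from
    amplitude-analyzed (sign-flipped if needed) samples, so the returned
    current carries the sign of the driving force.
    """
    if levels.n_levels < 1 or not levels.amplitude_measured:
        return None
    return IVPoint(voltage=voltage, unitary_current=levels.unitary_amplitude)


def slope_conductance(
    points: list[IVPoint], v_min: float = -40.0, v_max: float = 100.0
) -> ConductanceFit:
    """Unweighted OLS of unitary current on voltage; slope in pS.

    The window default matches the standard practice of fitting the
    ohmic region of the BK unitary i-V relation from -40 to +100 mV.
    """
    sel = [p for p in points if v_min <= p.voltage <= v_max]
    if len(sel) < 3:
        raise ValueError(
            f"slope conductance needs >= 3 I-V points in [{v_min}, {v_max}] mV, "
            f"got {len(sel)}"
        )
    v = np.array([p.voltage for p in sel])
    i = np.array([p.unitary_current for p in sel])
    res = _stats.linregress(v, i)
    return ConductanceFit(
        slope_conductance=float(res.slope * 1e3),  # pA/mV -> pS
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(sel),
    )
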