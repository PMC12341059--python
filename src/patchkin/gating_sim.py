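"""Continuous-time Markov simulation of BK channel gating.

Generates ground-truth gating paths (Gillespie sampling of a kinetic
scheme) and renders them into realistic noisy cell-attached current
sweeps: unitary current ``i = gamma * (V - V_rev)``, Gaussian recording
noise, and a zero-phase low-pass filter emulating the acquisition
filter. Calcium is not an explicit variable; its effect on gating is
folded into the effective rate constants.

All voltages are membrane potentials in mV. Any pipette-potential sign
convention is the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "RateFunction",
    "KineticScheme",
    "AcquisitionConfig",
    "StatePath",
    "Sweep",
    "Recording",
    "mean_dwell",
    "stationary_distribution",
    "stationary_po",
    "sample_path",
    "render_sweep",
    "simulate_recording",
    "wt_like_scheme",
    "n999s_like_scheme",
    "e656a_like_scheme",
    "conductance_assay_scheme",
    "two_state_scheme",
    "preset_scheme",
    "preset_config",
    "PRESETS",
]

DEFAULT_PROTOCOL = tuple(range(-40, 161, 20))  # mV, 20 mV steps


@dataclass(frozen=True)
class RateFunction:
    """Exponentially voltage-dependent transition rate.

    rate(V) = base_rate * exp(V / voltage_efold)

    ``base_rate`` is the rate at 0 mV in transitions/s; ``voltage_efold``
    is the signed e-fold voltage in mV (``inf`` => voltage-independent).
    """

    base_rate: float
    voltage_efold: float = math.inf

    def __post_init__(self) -> None:
        if not (self.base_rate > 0 and math.isfinite(self.base_rate)):
            raise ValueError("base_rate must be positive and finite")
        if self.voltage_efold == 0:
            raise ValueError("voltage_efold must be nonzero (use inf for none)")

    def __call__(self, voltage: float) -> float:
        if math.isinf(self.voltage_efold):
            return self.base_rate
        rate = self.base_rate * math.exp(voltage / self.voltage_efold)
        if not (rate > 0 and math.isfinite(rate)):
            raise ValueError(
                f"rate not positive/finite at {voltage} mV: {rate}"
            )
        return rate

    @classmethod
    def from_point(
        cls, rate: float, voltage: float, voltage_efold: float = math.inf
    ) -> "RateFunction":
        """Build a rate function pinned to ``rate`` at ``voltage`` mV."""
        if math.isinf(voltage_efold):
            return cls(rate)
        return cls(rate * math.exp(-voltage / voltage_efold), voltage_efold)


@dataclass(frozen=True)
class KineticScheme:
    """A gating scheme: labelled states, open/closed class, rate map.

    ``states`` maps label -> True if open (conducting); ``transitions``
    maps (from_label, to_label) -> RateFunction.
    """

    states: dict[str, bool]
    transitions: dict[tuple[str, str], RateFunction]
    scheme_name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("scheme needs at least 2 states")
        opens = [s for s, o in self.states.items() if o]
        closeds = [s for s, o in self.states.items() if not o]
        if not opens or not closeds:
            raise ValueError("scheme needs at least one open and one closed state")
        for (a, b) in self.transitions:
            if a == b:
                raise ValueError(f"self-transition {a}->{a} not allowed")
            if a not in self.states or b not in self.states:
                raise ValueError(f"transition {a}->{b} references unknown state")
        # connectivity of the undirected transition graph
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for (a, b) in self.transitions:
            adj[a].add(b)
            adj[b].add(a)
        seen = {next(iter(self.states))}
        stack = list(seen)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.states):
            raise ValueError("transition graph is not connected")

    @property
    def state_labels(self) -> list[str]:
        return list(self.states)

    @property
    def open_labels(self) -> list[str]:
        return [s for s, o in self.states.items() if o]

    def is_open(self, label: str) -> bool:
        return self.states[label]

    def generator(self, voltage: float) -> np.ndarray:
        """Infinitesimal generator Q at a voltage (rows sum to zero)."""
        labels = self.state_labels
        idx = {s: i for i, s in enumerate(labels)}
        q = np.zeros((len(labels), len(labels)))
        for (a, b), rf in self.transitions.items():
            q[idx[a], idx[b]] = rf(voltage)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings emulating cell-attached BK recordings.

    Defaults follow the recording protocol: 15 s sweeps from -40 to
    +160 mV in 20 mV steps, digitized at 50 kHz and low-pass filtered
    at 6 kHz, ~165 pS unitary conductance, reversal near 0 mV in
    near-symmetric K+.
    """

    sampling_rate: float = 50_000.0
    filter_cutoff: float | None = 6_000.0
    sweep_duration: float = 15.0
    protocol_voltages: tuple[float, ...] = DEFAULT_PROTOCOL
    holding_voltage: float = 0.0
    unitary_conductance: float = 165.0  # pS
    reversal_potential: float = 0.0  # mV
    noise_sd: float = 1.0  # pA
    n_channels: int = 1
    paxilline_block: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_cutoff is not None and not (
            self.sampling_rate > 2 * self.filter_cutoff
        ):
            raise ValueError("sampling_rate must exceed twice filter_cutoff")
        if self.sweep_duration <= 0:
            raise ValueError("sweep_duration must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.unitary_conductance <= 0:
            raise ValueError("unitary_conductance must be positive")

    def unitary_current(self, voltage: float) -> float:
        """Open-channel current in pA at a membrane potential (ohmic)."""
        return (
            self.unitary_conductance
            * (voltage - self.reversal_potential)
            * 1e-3
        )

    @property
    def n_samples(self) -> int:
        return round(self.sweep_duration * self.sampling_rate)


@dataclass(frozen=True)
class StatePath:
    """Ground-truth gating trajectory: ordered (state, dwell) segments."""

    states: tuple[str, ...]
    dwells: tuple[float, ...]  # s
    total_duration: float

    def __post_init__(self) -> None:
        if len(self.states) != len(self.dwells):
            raise ValueError("states and dwells length mismatch")
        if any(d <= 0 for d in self.dwells):
            raise ValueError("dwell durations must be positive")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("consecutive segments must differ in state")

    def open_fraction(self, scheme: KineticScheme) -> float:
        open_t = sum(
            d for s, d in zip(self.states, self.dwells) if scheme.is_open(s)
        )
        return open_t / self.total_duration

    def occupancy(self, scheme: KineticScheme, times: np.ndarray) -> np.ndarray:
        """0/1 open indicator of this path at sample times (s)."""
        edges = np.cumsum(self.dwells)
        seg = np.searchsorted(edges, times, side="right")
        seg = np.clip(seg, 0, len(self.states) - 1)
        is_open = np.array([scheme.is_open(s) for s in self.states], dtype=int)
        return is_open[seg]


@dataclass(frozen=True)
class Sweep:
    """One sampled current sweep at a fixed command voltage."""

    voltage: float  # mV
    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    truth_paths: tuple[StatePath, ...] | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sweep contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class Recording:
    """One patch: a sweep per protocol voltage plus acquisition config."""

    sweeps: tuple[Sweep, ...]
    config: AcquisitionConfig
    patch_id: str = "patch"
    scheme_name: str = "custom"

    def __post_init__(self) -> None:
        volts = [s.voltage for s in self.sweeps]
        if any(b <= a for a, b in zip(volts, volts[1:])):
            raise ValueError("sweep voltages must be strictly increasing")
        rates = {s.sampling_rate for s in self.sweeps}
        if len(rates) > 1:
            raise ValueError("all sweeps must share one sampling rate")

    @property
    def voltages(self) -> list[float]:
        return [s.voltage for s in self.sweeps]

    def sweep_at(self, voltage: float) -> Sweep:
        for s in self.sweeps:
            if s.voltage == voltage:
                return s
        raise KeyError(f"no sweep at {voltage} mV")


# ---------------------------------------------------------------------------
# analytic quantities

def _outgoing(scheme: KineticScheme, state: str):
    return [
        (b, rf) for (a, b), rf in scheme.transitions.items() if a == state
    ]


def mean_dwell(scheme: KineticScheme, state: str, voltage: float) -> float:
    """Mean sojourn time in a state: 1 / sum of outgoing rates."""
    if state not in scheme.states:
        raise KeyError(f"unknown state {state!r}")
    out = _outgoing(scheme, state)
    if not out:
        raise ValueError(f"state {state!r} is absorbing (no outgoing rates)")
    total = sum(rf(voltage) for _, rf in out)
    return 1.0 / total


def stationary_distribution(
    scheme: KineticScheme, voltage: float
) -> dict[str, float]:
    """Stationary distribution pi of the generator (pi Q = 0, pi 1 = 1)."""
    q = scheme.generator(voltage)
    n = q.shape[0]
    # every state must communicate (no absorbing/reducible structure)
    if np.any(np.diag(q) == 0):
        raise ValueError("scheme is reducible at this voltage (absorbing state)")
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-9):
        raise ValueError("scheme has no proper stationary distribution")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return dict(zip(scheme.state_labels, pi))


def stationary_po(scheme: KineticScheme, voltage: float) -> float:
    """Equilibrium single-channel open probability at a voltage."""
    pi = stationary_distribution(scheme, voltage)
    return float(sum(p for s, p in pi.items() if scheme.is_open(s)))


# ---------------------------------------------------------------------------
# stochastic simulation

def sample_path(
    scheme: KineticScheme,
    voltage: float,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
    start_state: str | None = None,
) -> StatePath:
    """Gillespie sample of the gating chain over ``duration`` seconds.

    Sojourns are exponential with the state's mean dwell; jumps follow
    the embedded chain (probabilities proportional to outgoing rates).
    The initial state is drawn from the stationary distribution unless
    ``start_state`` is given; the final sojourn is truncated at
    ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = scheme.state_labels
    out = {s: _outgoing(scheme, s) for s in labels}
    rates = {
        s: np.array([rf(voltage) for _, rf in o]) for s, o in out.items()
    }
    targets = {s: [b for b, _ in o] for s, o in out.items()}
    totals = {s: r.sum() for s, r in rates.items()}
    for s, t in totals.items():
        if t <= 0:
            raise ValueError(f"state {s!r} is absorbing")

    if start_state is None:
        pi = stationary_distribution(scheme, voltage)
        state = rng.choice(labels, p=[pi[s] for s in labels])
    else:
        if start_state not in scheme.states:
            raise KeyError(f"unknown state {start_state!r}")
        state = start_state

    states: list[str] = []
    dwells: list[float] = []
    t = 0.0
    while t < duration:
        dwell = rng.exponential(1.0 / totals[state])
        nxt_t = t + dwell
        if nxt_t >= duration:
            dwell = duration - t
            nxt_t = duration
        states.append(state)
        dwells.append(dwell)
        t = nxt_t
        if t >= duration:
            break
        p = rates[state] / totals[state]
        state = targets[state][rng.choice(len(p), p=p)]
    return StatePath(tuple(states), tuple(dwells), duration)


def _lowpass(samples: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    # zero-phase 4-pole Bessel: preserves dwell-boundary timing
    sos = signal.bessel(4, cutoff, fs=fs, output="sos", norm="mag")
    return signal.sosfiltfilt(sos, samples)


def render_sweep(
    paths: list[StatePath] | tuple[StatePath, ...],
    scheme: KineticScheme,
    voltage: float,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> Sweep:
    """Render per-channel gating paths into a sampled, noisy sweep.

    Per-sample current is (number of open channels) x unitary current,
    plus Gaussian noise of sd ``config.noise_sd``, then low-pass
    filtered at ``config.filter_cutoff`` (skipped when None).
    """
    if not paths:
        raise ValueError("at least one channel path required")
    for p in paths:
        if abs(p.total_duration - config.sweep_duration) > 1.0 / config.sampling_rate:
            raise ValueError("path duration does not match sweep_duration")
    times = np.arange(config.n_samples) / config.sampling_rate
    n_open = np.zeros(config.n_samples, dtype=int)
    for p in paths:
        n_open += p.occupancy(scheme, times)
    current = n_open * config.unitary_current(voltage)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        current = current + rng.normal(0.0, config.noise_sd, size=current.shape)
    if config.filter_cutoff is not None:
        current = _lowpass(current, config.filter_cutoff, config.sampling_rate)
    return Sweep(
        voltage=voltage,
        samples=np.asarray(current, dtype=float),
        sampling_rate=config.sampling_rate,
        truth_paths=tuple(paths),
    )


def simulate_recording(
    scheme: KineticScheme,
    config: AcquisitionConfig,
    patch_id: str = "patch",
) -> Recording:
    """Simulate one patch: an independent-channel sweep per protocol step.

    With ``paxilline_block`` all channels are pinned closed for the full
    sweep, emulating the pharmacological identity control.
    """
    ss = np.random.SeedSequence(config.seed)
    sweep_seeds = ss.spawn(len(config.protocol_voltages))
    closed0 = next(s for s, o in scheme.states.items() if not o)
    sweeps = []
    for voltage, sweep_ss in zip(config.protocol_voltages, sweep_seeds):
        child = sweep_ss.spawn(config.n_channels + 1)
        if config.paxilline_block:
            paths = [
                StatePath((closed0,), (config.sweep_duration,), config.sweep_duration)
                for _ in range(config.n_channels)
            ]
        else:
            paths = [
                sample_path(scheme, voltage, config.sweep_duration, np.random.default_rng(c))
                for c in child[:-1]
            ]
        noise_rng = np.random.default_rng(child[-1])
        sweeps.append(render_sweep(paths, scheme, voltage, config, rng=noise_rng))
    return Recording(
        sweeps=tuple(sweeps),
        config=config,
        patch_id=patch_id,
        scheme_name=scheme.scheme_name,
    )


# ---------------------------------------------------------------------------
# preset schemes
#
# Default gating scheme is the minimal linear chain C2 <-> C1 <-> O: one
# open state gives a single-exponential open-dwell distribution and the
# two closed states give a two-exponential closed-dwell distribution.
# Voltage dependence sits on the C1<->O step; the WT-like parameters put
# Po below 1e-4 at +60 mV and above 0.1 at +140 mV, so channels only
# activate above roughly +80 mV at endogenous calcium.

def _linear_c2c1o(
    name: str,
    k_c2c1: float,
    k_c1c2: float,
    k_c1o_at120: float,
    k_oc1_at120: float,
    efold_open: float = 12.0,
    efold_close: float = -30.0,
) -> KineticScheme:
    return KineticScheme(
        states={"C2": False, "C1": False, "O": True},
        transitions={
            ("C2", "C1"): RateFunction(k_c2c1),
            ("C1", "C2"): RateFunction(k_c1c2),
            ("C1", "O"): RateFunction.from_point(k_c1o_at120, 120.0, efold_open),
            ("O", "C1"): RateFunction.from_point(k_oc1_at120, 120.0, efold_close),
        },
        scheme_name=name,
    )


def wt_like_scheme() -> KineticScheme:
    """Control-like scheme: activates above ~+80 mV, tau_open ~2 ms at +120."""
    return _linear_c2c1o("wt", k_c2c1=110.0, k_c1c2=18_000.0,
                         k_c1o_at120=2_000.0, k_oc1_at120=500.0)


def n999s_like_scheme() -> KineticScheme:
    """GOF via destabilized closed states: closed->open rates raised ~3x.

    Shortens both closed components at unchanged conductance, raising Po
    at every activating voltage.
    """
    return _linear_c2c1o("n999s", k_c2c1=330.0, k_c1c2=18_000.0,
                         k_c1o_at120=6_000.0, k_oc1_at120=500.0)


def e656a_like_scheme() -> KineticScheme:
    """GOF via stabilized open state: open sojourns lengthened ~3x.

    Paired (in the preset config) with a reduced default channel count
    per patch, so the ensemble NPo gain is partly masked.
    """
    return _linear_c2c1o("e656a", k_c2c1=110.0, k_c1c2=18_000.0,
                         k_c1o_at120=2_000.0, k_oc1_at120=165.0)


def two_state_scheme(
    k_co: float = 200.0, k_oc: float = 200.0, name: str = "two_state"
) -> KineticScheme:
    """Minimal C <-> O scheme, voltage-independent; analytic everything."""
    return KineticScheme(
        states={"C": False, "O": True},
        transitions={
            ("C", "O"): RateFunction(k_co),
            ("O", "C"): RateFunction(k_oc),
        },
        scheme_name=name,
    )


def conductance_assay_scheme() -> KineticScheme:
    """Voltage-independent moderate-Po scheme for I-V characterization.

    Po = 0.5 and tau_open = 5 ms at every voltage, so a resolvable
    unitary amplitude is available across the whole -40..+100 mV slope
    fit range (a voltage-dependent scheme never opens at the lower end).
    """
    return two_state_scheme(k_co=200.0, k_oc=200.0, name="conductance_assay")


PRESETS = ("wt", "n999s", "e656a", "blocked", "conductance_assay")


def preset_scheme(name: str) -> KineticScheme:
    schemes = {
        "wt": wt_like_scheme,
        "n999s": n999s_like_scheme,
        "e656a": e656a_like_scheme,
        "blocked": wt_like_scheme,  # block is an acquisition condition
        "conductance_assay": conductance_assay_scheme,
    }
    try:
        return schemes[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}") from None


def preset_config(name: str, **overrides) -> AcquisitionConfig:
    """Acquisition defaults for a preset (channel counts per the study)."""
    base: dict = {"n_channels": 3}
    if name == "e656a":
        base["n_channels"] = 2  # reduced expression
    if name == "blocked":
        base["paxilline_block"] = True
    if name == "conductance_assay":
        base["n_channels"] = 1
    base.update(overrides)
    return AcquisitionConfig(**base)
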