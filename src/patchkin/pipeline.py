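"""End-to-end orchestration: simulate -> idealize -> metrics -> dwell -> stats.

``analyze_recording`` turns one patch's sweeps into idealized events,
NPo/Po tables, a channel count and an I-V/conductance fit;
``run_pipeline`` drives whole simulated cohorts from a config mapping
and writes tables, a JSON summary and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channel_metrics import (
    ConductanceFit,
    IVPoint,
    PatchSummary,
    SweepMetrics,
    estimate_n,
    npo,
    po_from_npo,
    slope_conductance,
    unitary_current,
)
from .dwell_fit import DwellFitResult, collect_dwells, fit_closed, fit_open, log_bin
from .gating_sim import (
    AcquisitionConfig,
    Recording,
    preset_config,
    preset_scheme,
    simulate_recording,
)
from .idealize import EventList, LevelSet, idealize
from .stats import compare_groups, normality_gate, per_voltage_compare

__all__ = [
    "PatchAnalysis",
    "analyze_recording",
    "dwell_summary",
    "run_pipeline",
    "conductance_assay",
    "closed_constant_assay",
]

logger = logging.getLogger("patchkin")


@dataclass(frozen=True)
class PatchAnalysis:
    """Everything the metrics stage derives from one patch."""

    summary: PatchSummary
    events_by_voltage: dict[float, EventList]
    levels_by_voltage: dict[float, LevelSet]
    metrics_by_voltage: dict[float, SweepMetrics]
    iv_points: tuple[IVPoint, ...]
    conductance: ConductanceFit | None


def analyze_recording(
    rec: Recording,
    iv_range: tuple[float, float] = (-40.0, 100.0),
    dead_time_s: float | None = None,
) -> PatchAnalysis:
    """Idealize every sweep of a patch and compute its summary statistics.

    Sweeps with negative driving force are sign-flipped before level
    detection (open levels must lie above baseline) and the unitary
    current sign is restored afterwards, so the I-V relation crosses
    zero at the reversal potential. Voltages where no open level
    resolves contribute no I-V point.
    """
    cfg = rec.config
    events_by_v: dict[float, EventList] = {}
    levels_by_v: dict[float, LevelSet] = {}
    metrics_by_v: dict[float, SweepMetrics] = {}
    iv_points: list[IVPoint] = []
    for sweep in rec.sweeps:
        drive = sweep.voltage - cfg.reversal_potential
        analysed = (
            replace(sweep, samples=-sweep.samples) if drive < 0 else sweep
        )
        expected = abs(cfg.unitary_current(sweep.voltage))
        # anchor the level lattice at the known closed level (0 pA after
        # the sign flip) and keep the peak-prominence floor low enough to
        # pick up minority levels at low or near-saturating Po
        events, levels = idealize(
            analysed,
            expected_unitary=expected if expected > 0 else None,
            dead_time_s=dead_time_s,
            filter_cutoff=cfg.filter_cutoff,
            prominence_frac=0.01,
            baseline_hint=0.0 if expected > 0 else None,
        )
        events_by_v[sweep.voltage] = events
        levels_by_v[sweep.voltage] = levels
        metrics_by_v[sweep.voltage] = npo(events, voltage=sweep.voltage)
        point = unitary_current(levels, sweep.voltage)
        if point is not None and drive != 0:
            iv_points.append(
                replace(
                    point,
                    unitary_current=np.sign(drive) * point.unitary_current,
                )
            )
    n = estimate_n(events_by_v)
    npo_by_v = {v: m.NPo for v, m in metrics_by_v.items()}
    po_by_v = (
        {v: po_from_npo(m, n) for v, m in metrics_by_v.items()}
        if n >= 1
        else {v: 0.0 for v in metrics_by_v}
    )
    fit: ConductanceFit | None
    try:
        fit = slope_conductance(iv_points, *iv_range)
    except ValueError:
        fit = None
    return PatchAnalysis(
        summary=PatchSummary(
            patch_id=rec.patch_id,
            n_channels=n,
            npo_by_voltage=npo_by_v,
            po_by_voltage=po_by_v,
        ),
        events_by_voltage=events_by_v,
        levels_by_voltage=levels_by_v,
        metrics_by_voltage=metrics_by_v,
        iv_points=tuple(iv_points),
        conductance=fit,
    )


def dwell_summary(
    analysis: PatchAnalysis,
    voltage: float,
    bins_per_decade: int = 10,
) -> dict[str, DwellFitResult]:
    """Open/closed dwell fits at one voltage of a single-channel patch."""
    events = analysis.events_by_voltage[voltage]
    out: dict[str, DwellFitResult] = {}
    for kind, fitter in (("open", fit_open), ("closed", fit_closed)):
        sample = collect_dwells(
            events, kind, source_patch=analysis.summary.patch_id, voltage=voltage
        )
        if len(sample) == 0:
            continue
        out[kind] = fitter(log_bin(sample, bins_per_decade), n_dwells=len(sample))
    return out


# ---------------------------------------------------------------------------
# parameter-recovery assays

IV_PROTOCOL = tuple(float(v) for v in range(-40, 101, 20))


def conductance_assay(
    unitary_conductance: float,
    seed: int,
    sweep_duration: float = 3.0,
    noise_sd: float = 1.0,
) -> float:
    """Recover the slope conductance of one simulated single-channel patch.

    Simulates a voltage-independent moderate-Po single channel over the
    -40..+100 mV protocol (so an open level resolves at every step),
    runs the full idealization pipeline, and returns the OLS slope of
    the recovered unitary i-V relation in pS.
    """
    scheme = preset_scheme("conductance_assay")
    cfg = AcquisitionConfig(
        sweep_duration=sweep_duration,
        protocol_voltages=IV_PROTOCOL,
        unitary_conductance=unitary_conductance,
        noise_sd=noise_sd,
        n_channels=1,
        seed=seed,
    )
    analysis = analyze_recording(simulate_recording(scheme, cfg))
    if analysis.conductance is None:
        raise RuntimeError("no conductance fit: too few resolvable I-V points")
    return analysis.conductance.slope_conductance


def closed_constant_assay(
    tau_fast: float,
    tau_slow: float,
    seed: int,
    n_dwells: int = 10_000,
    weight_fast: float = 0.5,
    bins_per_decade: int = 10,
) -> tuple[float, float]:
    """Recover two closed-time constants from a generated dwell sample.

    Draws ``n_dwells`` closed dwells from the two-exponential mixture,
    log-bins them, fits the two-component peak-at-tau function and
    returns (tau_fast, tau_slow) in seconds.
    """
    from .dwell_fit import DwellSample

    rng = np.random.default_rng(seed)
    fast = rng.random(n_dwells) < weight_fast
    dwells = np.where(
        fast,
        rng.exponential(tau_fast, n_dwells),
        rng.exponential(tau_slow, n_dwells),
    )
    fit = fit_closed(
        log_bin(DwellSample("closed", dwells), bins_per_decade),
        n_dwells=n_dwells,
    )
    if not fit.converged or len(fit.taus) < 2:
        raise RuntimeError("closed-dwell fit did not converge")
    return fit.taus[0], fit.taus[1]


# ---------------------------------------------------------------------------
# cohort pipeline

DEFAULT_CONFIG = {
    "seed": 1,
    "sweep_duration": 3.0,
    "groups": [
        {"label": "ctrl", "preset": "wt", "n_patches": 5},
        {"label": "n999s", "preset": "n999s", "n_patches": 5},
        {"label": "e656a", "preset": "e656a", "n_patches": 5},
        {"label": "blocked", "preset": "blocked", "n_patches": 5},
    ],
    "iv_range": [-40.0, 100.0],
    "npo_reference_voltage": 140.0,
    "dwell_voltage": 120.0,
    "bins_per_decade": 10,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            cfg = tomllib.loads(text)
        else:
            cfg = json.loads(text)
    else:
        cfg = dict(config)
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg)
    return merged


def _patch_seed(base_seed: int, group_idx: int, patch_idx: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, group_idx, patch_idx]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config, out_dir) -> dict:
    """Run the full cohort pipeline from a config mapping or file.

    Simulates every group's patches, idealizes and summarizes them,
    fits dwell-time constants on single-channel patches, runs the group
    comparison ladder, and writes CSV tables plus ``summary.json`` and
    ``run.log`` under ``out_dir``. Deterministic for a fixed config.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> dict:
    logger.info("patchkin %s; config: %s", __version__, json.dumps(cfg, sort_keys=True))
    curve_rows, n_rows, iv_rows, tau_rows = [], [], [], []
    analyses: dict[str, list[PatchAnalysis]] = {}
    for gi, group in enumerate(cfg["groups"]):
        label, preset = group["label"], group["preset"]
        scheme = preset_scheme(preset)
        analyses[label] = []
        for pi in range(int(group["n_patches"])):
            seed = _patch_seed(int(cfg["seed"]), gi, pi)
            acq = preset_config(
                preset,
                sweep_duration=float(cfg["sweep_duration"]),
                seed=seed,
                **{
                    k: group[k]
                    for k in ("n_channels", "noise_sd", "unitary_conductance")
                    if k in group
                },
            )
            patch_id = f"{label}_{pi:02d}"
            logger.info("simulating %s (preset=%s seed=%d)", patch_id, preset, seed)
            rec = simulate_recording(scheme, acq, patch_id=patch_id)
            an = analyze_recording(rec, iv_range=tuple(cfg["iv_range"]))
            analyses[label].append(an)
            n_rows.append((label, patch_id, an.summary.n_channels))
            for v, value in an.summary.npo_by_voltage.items():
                curve_rows.append((label, patch_id, v, value, "NPo"))
            for v, value in an.summary.po_by_voltage.items():
                curve_rows.append((label, patch_id, v, value, "Po"))
            for pt in an.iv_points:
                iv_rows.append((label, patch_id, pt.voltage, pt.unitary_current))
            if an.summary.is_single_channel:
                fits = dwell_summary(
                    an, float(cfg["dwell_voltage"]), int(cfg["bins_per_decade"])
                )
                for kind, fit in fits.items():
                    if fit.converged and fit.components:
                        taus = fit.taus
                        tau_rows.append(
                            (
                                label, patch_id, kind,
                                taus[0],
                                taus[1] if len(taus) > 1 else np.nan,
                                fit.weights[0],
                            )
                        )
    curves = pd.DataFrame(
        curve_rows, columns=["group", "patch_id", "voltage", "value", "metric"]
    )
    curves.to_csv(out / "curves.csv", index=False)
    pd.DataFrame(n_rows, columns=["group", "patch_id", "n_channels"]).to_csv(
        out / "channels_per_patch.csv", index=False
    )
    pd.DataFrame(
        iv_rows, columns=["group", "patch_id", "voltage_mV", "unitary_current_pA"]
    ).to_csv(out / "iv_points.csv", index=False)
    pd.DataFrame(
        tau_rows,
        columns=["group", "patch_id", "kind", "tau1_s", "tau2_s", "weight1"],
    ).to_csv(out / "dwell_taus.csv", index=False)

    # group statistics on NPo at the reference voltage
    v_ref = float(cfg["npo_reference_voltage"])
    npo_ref = curves[(curves["metric"] == "NPo") & (curves["voltage"] == v_ref)]
    summary: dict = {
        "config": cfg,
        "version": __version__,
        "n_channels_mean": {
            label: float(np.mean([a.summary.n_channels for a in ans]))
            for label, ans in analyses.items()
        },
        "conductance_pS": {
            label: [
                a.conductance.slope_conductance
                for a in ans
                if a.conductance is not None
            ]
            for label, ans in analyses.items()
        },
    }
    if npo_ref["group"].nunique() >= 2:
        route = normality_gate(npo_ref)
        comp = compare_groups(npo_ref, route)
        summary["npo_comparison"] = {
            "voltage_mV": v_ref,
            "route": comp.route,
            "test": comp.test_name,
            "omnibus_p": comp.omnibus_p,
            "degenerate": comp.degenerate,
            "pairwise": [list(p) for p in comp.pairwise],
        }
        if comp.degenerate:
            logger.warning("NPo comparison degenerate (constant data)")
    npo_curves = curves[curves["metric"] == "NPo"].rename(columns={})
    labels = [g["label"] for g in cfg["groups"]]
    per_voltage = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            try:
                res = per_voltage_compare(npo_curves, (a, b))
            except ValueError as exc:
                logger.warning("per-voltage %s vs %s skipped: %s", a, b, exc)
                continue
            per_voltage[f"{a}|{b}"] = [
                {
                    "voltage_mV": r.voltage,
                    "raw_p": r.raw_p,
                    "adjusted_p": r.adjusted_p,
                }
                for r in res
            ]
    summary["per_voltage_npo"] = per_voltage
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %s", out)
    return summary
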