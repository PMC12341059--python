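"""On-disk formats: recording bundles, event lists, histograms.

A recording bundle is a directory holding one CSV per sweep (columns
``time_s, current_pA``), a ``config.json`` sidecar with the acquisition
settings, and, for simulated data, a ``truth_events.csv`` ground-truth
gating table (``voltage_mV, channel, state, start_s, duration_s``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gating_sim import AcquisitionConfig, Recording, StatePath, Sweep
from .idealize import AllPointsHistogram, EventList

__all__ = [
    "save_recording",
    "load_recording",
    "save_events",
    "load_events",
    "save_histogram",
]


def _sweep_filename(voltage: float) -> str:
    sign = "m" if voltage < 0 else "p"
    return f"sweep_{sign}{abs(voltage):07.2f}mV.csv"


def save_recording(rec: Recording, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sweep in rec.sweeps:
        df = pd.DataFrame(
            {"time_s": sweep.times, "current_pA": sweep.samples}
        )
        df.to_csv(out / _sweep_filename(sweep.voltage), index=False)
    sidecar = {
        "patch_id": rec.patch_id,
        "scheme_name": rec.scheme_name,
        "config": dataclasses.asdict(rec.config),
    }
    (out / "config.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    truth_rows = []
    for sweep in rec.sweeps:
        if sweep.truth_paths is None:
            continue
        for ch, path in enumerate(sweep.truth_paths):
            start = 0.0
            for state, dwell in zip(path.states, path.dwells):
                truth_rows.append(
                    (sweep.voltage, ch, state, start, dwell)
                )
                start += dwell
    if truth_rows:
        pd.DataFrame(
            truth_rows,
            columns=["voltage_mV", "channel", "state", "start_s", "duration_s"],
        ).to_csv(out / "truth_events.csv", index=False)
    return out


def load_recording(in_dir) -> Recording:
    src = Path(in_dir)
    sidecar = json.loads((src / "config.json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["protocol_voltages"] = tuple(cfg_dict["protocol_voltages"])
    config = AcquisitionConfig(**cfg_dict)
    truth: dict[float, list[StatePath]] = {}
    truth_file = src / "truth_events.csv"
    if truth_file.exists():
        tdf = pd.read_csv(truth_file)
        for (v, _ch), seg in tdf.groupby(["voltage_mV", "channel"], sort=True):
            seg = seg.sort_values("start_s")
            path = StatePath(
                tuple(seg["state"]),
                tuple(seg["duration_s"].astype(float)),
                float(seg["duration_s"].sum()),
            )
            truth.setdefault(float(v), []).append(path)
    sweeps = []
    for csv_path in sorted(src.glob("sweep_*mV.csv")):
        df = pd.read_csv(csv_path)
        samples = df["current_pA"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(df["time_s"].to_numpy(dtype=float))))
        stem = csv_path.stem.removeprefix("sweep_").removesuffix("mV")
        voltage = float(stem[1:]) * (-1 if stem[0] == "m" else 1)
        paths = truth.get(voltage)
        sweeps.append(
            Sweep(
                voltage=voltage,
                samples=samples,
                sampling_rate=1.0 / dt,
                truth_paths=tuple(paths) if paths else None,
            )
        )
    sweeps.sort(key=lambda s: s.voltage)
    return Recording(
        sweeps=tuple(sweeps),
        config=config,
        patch_id=sidecar.get("patch_id", "patch"),
        scheme_name=sidecar.get("scheme_name", "custom"),
    )


def save_events(events: EventList, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "level": events.levels,
            "start_s": events.starts,
            "duration_s": events.durations,
        }
    ).to_csv(path, index=False)
    return path


def load_events(path, dead_time: float = 0.0) -> EventList:
    df = pd.read_csv(path)
    durations = df["duration_s"].to_numpy(dtype=float)
    return EventList(
        levels=df["level"].to_numpy(dtype=int),
        starts=df["start_s"].to_numpy(dtype=float),
        durations=durations,
        sweep_duration=float(durations.sum()),
        dead_time=dead_time,
    )


def save_histogram(hist: AllPointsHistogram, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"bin_center_pA": hist.bin_centers, "count": hist.counts}
    ).to_csv(path, index=False)
    return path
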