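"""CSV / JSON round-trip I/O and run logging.

Dialect: comma separation, '.' decimal, mandatory header row, '#' comment
lines permitted.  Floats are written with repr-precision (%.17g) so every
numeric payload round-trips bit-exactly.  Temperatures are degC, lengths
metres, times seconds (documented in the column names).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bioheat import FieldHistory, SimGrid, TemperatureField
from .thermal import TemperatureTrace, ThermalFrameStack
from .tumor_stats import (GRADE_SERIES_COLUMNS, GradeSeries,
                          MethodOutcomeTable)

__all__ = [
    "FLOAT_FORMAT",
    "write_traces_csv", "read_traces_csv",
    "write_field_csv", "read_field_csv",
    "write_grades_csv", "read_grades_csv",
    "write_outcomes_csv", "read_outcomes_csv",
    "write_frames_dir", "read_frames_dir",
    "write_run_json", "RunLog",
]

FLOAT_FORMAT = "%.17g"


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip",
                           **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc


# -- traces -----------------------------------------------------------------

def write_traces_csv(path, traces: Sequence[TemperatureTrace]) -> None:
    if not traces:
        raise ValueError("no traces to write")
    times = traces[0].times
    for tr in traces:
        if tr.times.shape != times.shape or not np.array_equal(tr.times, times):
            raise ValueError("all traces must share one time axis")
    data = {"time_s": times}
    for i, tr in enumerate(traces):
        label = tr.label if tr.label is not None else f"trace{i}"
        data[f"T_{label}_C"] = tr.temperatures
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        if traces[0].baseline is not None:
            fh.write(f"# baseline_C = {FLOAT_FORMAT % traces[0].baseline}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_traces_csv(path) -> list[TemperatureTrace]:
    baseline = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# baseline_C"):
            baseline = float(first.split("=", 1)[1])
    df = _read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        label = col[2:-2] if col.startswith("T_") and col.endswith("_C") else col
        traces.append(TemperatureTrace(times=df["time_s"].to_numpy(),
                                       temperatures=df[col].to_numpy(),
                                       baseline=baseline, label=label))
    return traces


# -- fields -----------------------------------------------------------------

def write_field_csv(path, field: TemperatureField, grid: SimGrid) -> None:
    """Long-format snapshot: r_m, z_m, T_C (time in a comment header)."""
    rr, zz = np.meshgrid(grid.r, grid.z)
    df = pd.DataFrame({"r_m": rr.ravel(), "z_m": zz.ravel(),
                       "T_C": field.T.ravel()})
    with open(path, "w") as fh:
        fh.write(f"# time_s = {FLOAT_FORMAT % field.time}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_field_csv(path) -> tuple[TemperatureField, np.ndarray, np.ndarray]:
    """Returns (field, r_nodes, z_nodes)."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# time_s"):
        raise ValueError(f"{path}: missing '# time_s' header")
    time = float(first.split("=", 1)[1])
    df = _read_csv(path)
    r = np.unique(df["r_m"].to_numpy())
    z = np.unique(df["z_m"].to_numpy())
    if df.shape[0] != r.size * z.size:
        raise ValueError(f"{path}: field rows do not form a full (r, z) grid")
    T = df["T_C"].to_numpy().reshape(z.size, r.size)
    return TemperatureField(T=T, time=time), r, z


def write_history_dir(outdir, history: FieldHistory) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for snap in history:
        p = outdir / f"field_t{snap.time:.6f}.csv"
        write_field_csv(p, snap, history.grid)
        paths.append(p)
    return paths


# -- grades -----------------------------------------------------------------

def write_grades_csv(path, series: GradeSeries) -> None:
    series.df.to_csv(path, index=False, columns=GRADE_SERIES_COLUMNS)


def read_grades_csv(path) -> GradeSeries:
    df = _read_csv(path)
    missing = [c for c in GRADE_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["fluorescence_detected"] = df["fluorescence_detected"].astype(bool)
    try:
        return GradeSeries(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# -- implantation outcomes --------------------------------------------------

def write_outcomes_csv(path, table: MethodOutcomeTable) -> None:
    table.df.to_csv(path, index=False)


def read_outcomes_csv(path) -> MethodOutcomeTable:
    try:
        return MethodOutcomeTable(_read_csv(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# -- frame stacks -----------------------------------------------------------

def write_frames_dir(outdir, stack: ThermalFrameStack) -> None:
    """One CSV per frame plus a frames_meta.json with times and pitch."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        np.savetxt(outdir / f"frame_{i:04d}.csv", frame, delimiter=",",
                   fmt=FLOAT_FORMAT,
                   header="2-D temperature frame, degC", comments="# ")
    meta = {"times_s": [float(t) for t in stack.times],
            "pixel_pitch_m": stack.pixel_pitch,
            "laser_on_time_s": stack.laser_on_time}
    (outdir / "frames_meta.json").write_text(json.dumps(meta, indent=1))


def read_frames_dir(indir, pixel_pitch: float | None = None
                    ) -> ThermalFrameStack:
    indir = Path(indir)
    meta_path = indir / "frames_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if pixel_pitch is None:
        pixel_pitch = meta.get("pixel_pitch_m")
    if pixel_pitch is None:
        raise ValueError(f"{indir}: pixel pitch neither given nor in metadata")
    frame_paths = sorted(indir.glob("frame_*.csv"))
    if not frame_paths:
        raise ValueError(f"{indir}: no frame_*.csv files found")
    frames = []
    for p in frame_paths:
        arr = np.loadtxt(p, delimiter=",", comments="#", ndmin=2)
        if frames and arr.shape != frames[0].shape:
            raise ValueError(
                f"{p}: frame shape {arr.shape} mismatches first frame "
                f"{frames[0].shape}")
        frames.append(arr)
    times = np.asarray(meta.get("times_s", np.arange(len(frames))), float)
    return ThermalFrameStack(times=times, frames=np.stack(frames),
                             pixel_pitch=float(pixel_pitch),
                             laser_on_time=meta.get("laser_on_time_s"))


# -- run metadata -----------------------------------------------------------

def write_run_json(path, parameters: dict, **extra) -> None:
    """Deterministic parameter echo (no timestamps, stable key order)."""
    from . import __version__
    payload = {"code_version": __version__,
               "parameters": dict(sorted(parameters.items()))}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


class RunLog:
    """Append-only timestamped event log; one per run."""

    def __init__(self, path):
        self.path = Path(path)
        self.event("run log opened")

    def event(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}  {message}\n")
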