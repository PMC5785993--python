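"""Thermal-field summaries: probe traces, peaks, super-threshold extent.

Works on two kinds of input: simulated :class:`~enafl.bioheat.FieldHistory`
objects (axisymmetric (r, z) snapshots) and :class:`ThermalFrameStack`
objects, i.e. time-stamped 2-D pixel frames as produced by an infrared
camera or by the synthetic thermography generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bioheat import FieldHistory

__all__ = [
    "ProbePoint",
    "TemperatureTrace",
    "ThermalFrameStack",
    "PeakSummary",
    "TraceMetrics",
    "default_probe_points",
    "probe_traces",
    "peak_summary",
    "superthreshold_extent",
    "trace_metrics",
    "rank_peak_by_site",
]


@dataclass(frozen=True)
class ProbePoint:
    """A monitoring point at radial ``distance`` from the spot centre and
    ``depth`` below the surface (both metres)."""

    label: str
    distance: float
    depth: float = 0.0

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError(f"probe {self.label!r}: distance must be >= 0")
        if self.depth < 0:
            raise ValueError(f"probe {self.label!r}: depth must be >= 0")


def default_probe_points() -> list[ProbePoint]:
    """The four standard surface probes a-d at 0, 100, 150 and 200 um."""
    return [ProbePoint("a", 0.0), ProbePoint("b", 100.0e-6),
            ProbePoint("c", 150.0e-6), ProbePoint("d", 200.0e-6)]


@dataclass(frozen=True)
class TemperatureTrace:
    times: np.ndarray
    temperatures: np.ndarray
    baseline: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", T)
        if t.size != T.size:
            raise ValueError("times and temperatures must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")


@dataclass(frozen=True)
class ThermalFrameStack:
    """Time-stamped 2-D temperature frames on a fixed pixel grid."""

    times: np.ndarray
    frames: np.ndarray          # shape (n_t, n_rows, n_cols), degC
    pixel_pitch: float          # metres per pixel
    laser_on_time: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_t, rows, cols) array")
        if f.shape[0] != t.size:
            raise ValueError("one time stamp per frame required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    def baseline_frame(self) -> np.ndarray:
        """Mean of pre-heating frames if a laser-on time is known, else the
        first frame (standard thermography baseline practice)."""
        if self.laser_on_time is not None:
            pre = self.frames[self.times < self.laser_on_time]
            if pre.shape[0] > 0:
                return pre.mean(axis=0)
        return self.frames[0]

    def pixel_trace(self, row: int, col: int, label: str | None = None,
                    baseline: float | None = None) -> TemperatureTrace:
        if baseline is None:
            baseline = float(self.baseline_frame()[row, col])
        return TemperatureTrace(times=self.times,
                                temperatures=self.frames[:, row, col],
                                baseline=baseline, label=label)


@dataclass(frozen=True)
class PeakSummary:
    temperature: float
    time: float
    location: tuple          # (r, z) metres for histories; (row, col) for stacks


@dataclass(frozen=True)
class TraceMetrics:
    delta_peak: float        # degC above baseline
    time_to_peak: float      # s (first time the maximum is attained)
    return_time: float | None  # s, first post-peak time back within the band
    returned: bool


# ---------------------------------------------------------------------------

def _bilinear_weights(grid_axis: np.ndarray, x: float):
    """Index pair and weight for linear interpolation on a 1-D node axis."""
    i = int(np.searchsorted(grid_axis, x, side="right") - 1)
    i = min(max(i, 0), grid_axis.size - 2)
    span = grid_axis[i + 1] - grid_axis[i]
    w = (x - grid_axis[i]) / span
    return i, float(w)


def probe_traces(history: FieldHistory,
                 points: Sequence[ProbePoint] | None = None
                 ) -> list[TemperatureTrace]:
    """Bilinearly interpolate each snapshot at each probe point.

    Defaults to the four standard surface probes a-d.  A probe outside the
    simulated domain is rejected by label.
    """
    if points is None:
        points = default_probe_points()
    grid = history.grid
    weights = []
    for p in points:
        if p.distance > grid.r[-1] or p.depth > grid.z[-1]:
            raise ValueError(f"probe point {p.label!r} lies outside the grid")
        ir, wr = _bilinear_weights(grid.r, p.distance)
        iz, wz = _bilinear_weights(grid.z, p.depth)
        weights.append((ir, wr, iz, wz))

    times = history.times
    baseline = history.baseline
    traces = []
    for p, (ir, wr, iz, wz) in zip(points, weights):
        vals = np.empty(times.size)
        for n, snap in enumerate(history):
            T = snap.T
            vals[n] = ((1 - wz) * ((1 - wr) * T[iz, ir] + wr * T[iz, ir + 1])
                       + wz * ((1 - wr) * T[iz + 1, ir] + wr * T[iz + 1, ir + 1]))
        traces.append(TemperatureTrace(times=times, temperatures=vals,
                                       baseline=baseline, label=p.label))
    return traces


def peak_summary(obj: FieldHistory | ThermalFrameStack) -> PeakSummary:
    """Global space-time maximum; ties broken by earliest time, then by
    smallest radius/depth (histories) or row-major pixel order (stacks)."""
    if isinstance(obj, FieldHistory):
        best = None
        for snap in obj:
            m = snap.T.max()
            if best is None or m > best[0]:
                # within the snapshot prefer smallest radius then depth
                cand = np.argwhere(snap.T == m)
                iz, ir = min(cand.tolist(), key=lambda p: (p[1], p[0]))
                best = (m, snap.time, (float(obj.grid.r[ir]),
                                       float(obj.grid.z[iz])))
        return PeakSummary(temperature=float(best[0]), time=float(best[1]),
                           location=best[2])
    if isinstance(obj, ThermalFrameStack):
        if obj.frames.shape[0] == 0:
            raise ValueError("empty frame stack")
        flat = obj.frames.reshape(obj.frames.shape[0], -1)
        m = flat.max()
        n_t = int(np.argmax(flat.max(axis=1) == m))  # earliest frame at max
        pix = int(np.argmax(flat[n_t] == m))         # row-major first
        row, col = np.unravel_index(pix, obj.frames.shape[1:])
        return PeakSummary(temperature=float(m), time=float(obj.times[n_t]),
                           location=(int(row), int(col)))
    raise TypeError("expected a FieldHistory or ThermalFrameStack")


def superthreshold_extent(history: FieldHistory, threshold: float) -> float:
    """Maximal lateral width (m) of the region exceeding ``threshold`` degC.

    Over all snapshots and depths this returns 2 * max{r : T(r, z, t) >
    threshold}, with the outermost crossing radius refined by linear
    interpolation between neighbouring nodes; 0 if never exceeded.
    """
    baseline = history.baseline
    if threshold <= baseline:
        raise ValueError(
            f"threshold {threshold} degC must exceed the baseline "
            f"{baseline} degC (the extent would be the whole domain)")
    r = history.grid.r
    r_max = 0.0
    for snap in history:
        hot = snap.T > threshold
        for iz in np.nonzero(hot.any(axis=1))[0]:
            row = snap.T[iz]
            i_last = int(np.nonzero(row > threshold)[0][-1])
            if i_last == r.size - 1:
                r_cross = r[-1]
            else:
                f = (row[i_last] - threshold) / (row[i_last] - row[i_last + 1])
                r_cross = r[i_last] + f * (r[i_last + 1] - r[i_last])
            r_max = max(r_max, float(r_cross))
    return 2.0 * r_max


def trace_metrics(trace: TemperatureTrace, *, baseline: float | None = None,
                  return_band: float = 1.0) -> TraceMetrics:
    """Peak rise, time to peak, and return-to-baseline time of one trace.

    ``baseline`` defaults to the trace's stored baseline, falling back to the
    first sample.  The return time is the first time at or after the peak at
    which the temperature is within ``return_band`` degC of baseline.
    """
    T = trace.temperatures
    if T.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if baseline is None:
        baseline = trace.baseline if trace.baseline is not None else float(T[0])
    i_peak = int(np.argmax(T))
    delta = float(T[i_peak] - baseline)
    post = np.abs(T[i_peak:] - baseline) <= return_band
    if post.any():
        i_ret = i_peak + int(np.argmax(post))
        return TraceMetrics(delta_peak=delta,
                            time_to_peak=float(trace.times[i_peak]),
                            return_time=float(trace.times[i_ret]),
                            returned=True)
    return TraceMetrics(delta_peak=delta,
                        time_to_peak=float(trace.times[i_peak]),
                        return_time=None, returned=False)


def rank_peak_by_site(traces: Sequence[TemperatureTrace]) -> list[str]:
    """Site labels ordered by decreasing peak temperature rise (stable)."""
    if len(traces) < 1:
        raise ValueError("at least one labelled trace required")
    labels = [t.label for t in traces]
    if any(lab is None for lab in labels):
        raise ValueError("every trace must carry a site label")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate site labels")
    deltas = [trace_metrics(t).delta_peak for t in traces]
    order = sorted(range(len(traces)), key=lambda i: -deltas[i])
    return [labels[i] for i in order]
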