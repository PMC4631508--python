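"""Temporal alignment of shape traces and group statistics.

Dividing cells enter the movie at arbitrary phases, so traces are aligned
to the onset of anaphase elongation — the "shoulder" of the aspect-ratio
curve.  The shoulder is the first time point whose forward 10-minute
window slope exceeds the backward 10-minute window slope by a set
fraction (20% for wild type, 60% for mutants, whose elongation is
weaker).  The same inflection rule applied to the convex hull volume
ratio (CHVR) calls the start of cytokinesis.  Aligned cohorts are
averaged per time point with standard errors, and genotypes are compared
on per-cell percent changes with a pooled-variance two-sample Student
t-test.

The raw slope-ratio rule is ill-posed where the backward slope is zero or
negative (flat baselines make the ratio blow up a full window early), so
detection adds two guards, documented in the methods note: the backward
slope is clamped to a small positive floor, and the forward slope must
reach 90% of the trace's maximum forward slope, which pins the call to
the junction of flat-then-rising traces within about one frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trace import DESCRIPTORS, GeometryTrace

__all__ = [
    "AlignmentSpec",
    "AlignedGroup",
    "window_slope",
    "detect_shoulder",
    "detect_cytokinesis_onset",
    "align_and_average",
    "percent_change",
    "peak_rate",
    "compare_groups",
]


@dataclass(frozen=True)
class AlignmentSpec:
    """Shoulder-detection parameters.

    ``window`` is the slope window in seconds (default 600 s = 10 min);
    ``slope_ratio_threshold`` the required fractional slope increase
    (0.20 for wild type, 0.60 for mutants); ``signal`` the descriptor the
    shoulder is read from; ``peak_fraction`` the fraction of the trace's
    maximum forward slope the candidate must reach (the flat-baseline
    guard).
    """

    window: float = 600.0
    slope_ratio_threshold: float = 0.20
    signal: str = "aspect_ratio"
    peak_fraction: float = 0.9

    def __post_init__(self):
        if self.slope_ratio_threshold <= 0:
            raise ValueError("slope_ratio_threshold must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")


@dataclass
class AlignedGroup:
    """Aligned trace cohort with per-time mean and SEM per descriptor.

    ``summary`` has one row per aligned time covered by >= 2 traces with
    ``<descriptor>_mean``/``<descriptor>_sem``/``n`` columns; ``t0`` maps
    cell id to the subtracted reference time (s); ``excluded`` lists cell
    ids with no shoulder call.
    """

    traces: list[GeometryTrace]
    t0: dict[int, float]
    summary: pd.DataFrame
    excluded: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.traces)


def window_slope(values, times, index: int, direction: str,
                 window: float) -> float:
    """OLS slope (units per minute) over one side window at ``index``.

    The sample at ``index`` belongs to both the forward and the backward
    window (10 min at 60 s spacing = 11 samples).  Raises if the window
    does not fit inside the series.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    t0 = times[index]
    if direction == "forward":
        sel = (times >= t0) & (times <= t0 + window + 1e-9)
        if times[-1] < t0 + window - 1e-9:
            raise ValueError("forward window exceeds series bounds")
    elif direction == "backward":
        sel = (times <= t0) & (times >= t0 - window - 1e-9)
        if times[0] > t0 - window + 1e-9:
            raise ValueError("backward window exceeds series bounds")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    t = times[sel] / 60.0
    v = values[sel]
    t = t - t.mean()
    return float((t * (v - v.mean())).sum() / (t * t).sum())


def _forward_backward_slopes(values, times, window):
    """Slopes at every index where both windows fit; NaN elsewhere."""
    n = len(values)
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    for i in range(n):
        try:
            fwd[i] = window_slope(values, times, i, "forward", window)
            bwd[i] = window_slope(values, times, i, "backward", window)
        except ValueError:
            continue
    return fwd, bwd


def detect_shoulder(trace: GeometryTrace,
                    spec: AlignmentSpec | None = None) -> int | None:
    """Index of the elongation-onset shoulder, or ``None`` if no call.

    The shoulder is the earliest index where the forward-window slope is
    positive, exceeds ``(1 + threshold)`` times the (floored) backward
    slope, and reaches ``peak_fraction`` of the trace's maximum forward
    slope.  Strictly linear traces never satisfy the ratio and yield a
    no-call.
    """
    spec = spec or AlignmentSpec()
    values = trace.values(spec.signal)
    fwd, bwd = _forward_backward_slopes(values, trace.times, spec.window)
    valid = ~np.isnan(fwd) & ~np.isnan(bwd)
    if not valid.any():
        return None
    # slope floor: 1e-6 of the signal's dynamic range per minute
    eps = 1e-6 * max(float(values.max() - values.min()), 1e-300)
    peak = np.nanmax(fwd)
    if not (peak > 0):
        return None
    hits = (valid & (fwd > 0)
            & (fwd >= (1.0 + spec.slope_ratio_threshold)
               * np.maximum(bwd, eps))
            & (fwd >= spec.peak_fraction * peak))
    idx = np.flatnonzero(hits)
    return int(idx[0]) if len(idx) else None


def detect_cytokinesis_onset(trace: GeometryTrace,
                             spec: AlignmentSpec | None = None) -> int | None:
    """Start of cytokinesis: the same inflection rule on the CHVR series."""
    spec = spec or AlignmentSpec(signal="chvr")
    if spec.signal != "chvr":
        spec = AlignmentSpec(window=spec.window,
                             slope_ratio_threshold=spec.slope_ratio_threshold,
                             signal="chvr",
                             peak_fraction=spec.peak_fraction)
    return detect_shoulder(trace, spec)


def align_and_average(traces: list[GeometryTrace],
                      spec: AlignmentSpec | None = None,
                      descriptors: list[str] | None = None) -> AlignedGroup:
    """Shift each trace so its shoulder is t = 0 and average per time point.

    Traces with no shoulder call are excluded (and reported); fewer than
    two callable traces is an error.  Mean and SEM are reported only at
    aligned times covered by at least two traces.
    """
    spec = spec or AlignmentSpec()
    descriptors = descriptors or list(DESCRIPTORS)
    aligned, t0s, excluded = [], {}, []
    for tr in traces:
        i0 = detect_shoulder(tr, spec)
        if i0 is None:
            excluded.append(tr.cell_id)
            continue
        t0 = float(tr.times[i0])
        t0s[tr.cell_id] = t0
        aligned.append(tr.shifted(t0))
    if len(aligned) < 2:
        raise ValueError(
            f"need >= 2 traces with a shoulder call, got {len(aligned)}")
    dt = aligned[0].frame_interval
    frames = sorted({int(round(t / dt)) for tr in aligned for t in tr.times})
    rows = []
    for fr in frames:
        t = fr * dt
        row = {"time_s": t}
        samples = {d: [] for d in descriptors}
        for tr in aligned:
            j = np.flatnonzero(np.isclose(tr.times, t, atol=dt * 1e-6))
            if len(j):
                for d in descriptors:
                    samples[d].append(tr.values(d)[j[0]])
        ns = {len(v) for v in samples.values()}
        n = ns.pop()
        if n < 2:
            continue
        row["n"] = n
        for d in descriptors:
            v = np.asarray(samples[d], dtype=float)
            row[f"{d}_mean"] = v.mean()
            row[f"{d}_sem"] = v.std(ddof=1) / math.sqrt(n)
        rows.append(row)
    summary = pd.DataFrame(rows)
    return AlignedGroup(traces=aligned, t0=t0s, summary=summary,
                        excluded=excluded)


def percent_change(group: AlignedGroup, descriptor: str,
                   t_start: float = 0.0,
                   t_end: float = 25.0 * 60.0) -> pd.DataFrame:
    """Per-trace percent change of a descriptor between two aligned times.

    Returns one row per covering trace (cell_id, value at start/end,
    percent change); the group mean and SEM live in ``.attrs``.  Traces
    not covering the interval are skipped.
    """
    rows = []
    for tr in group.traces:
        dt = tr.frame_interval
        js = np.flatnonzero(np.isclose(tr.times, t_start, atol=dt * 1e-6))
        je = np.flatnonzero(np.isclose(tr.times, t_end, atol=dt * 1e-6))
        if not (len(js) and len(je)):
            continue
        v = tr.values(descriptor)
        v0, v1 = float(v[js[0]]), float(v[je[0]])
        rows.append({"cell_id": tr.cell_id, "start": v0, "end": v1,
                     "percent_change": 100.0 * (v1 - v0) / v0})
    out = pd.DataFrame(rows)
    if len(out):
        pc = out["percent_change"].to_numpy()
        out.attrs["mean"] = float(pc.mean())
        out.attrs["sem"] = (float(pc.std(ddof=1) / math.sqrt(len(pc)))
                            if len(pc) > 1 else float("nan"))
    return out


def peak_rate(group: AlignedGroup, descriptor: str = "surface_area",
              smooth_points: int = 5) -> float:
    """Peak rate of increase of the group-mean descriptor (units/min).

    The mean curve is smoothed with a ``smooth_points`` moving average
    before central differencing; the maximum of the derivative over the
    aligned times is returned.
    """
    s = group.summary
    t = s["time_s"].to_numpy(dtype=float) / 60.0
    v = s[f"{descriptor}_mean"].to_numpy(dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 aligned time points")
    if smooth_points > 1:
        k = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        vp = np.pad(v, pad, mode="edge")
        v = np.convolve(vp, k, mode="valid")
    dv = np.gradient(v, t)
    return float(dv.max())


def compare_groups(a, b, descriptor: str | None = None) -> tuple[float, float]:
    """Two-sample pooled-variance Student t-test on percent-change samples.

    ``a``/``b`` are either :class:`AlignedGroup` objects (then
    ``descriptor`` selects the percent-change samples, over the default
    0-25 min interval) or 1-D sample arrays.  Returns ``(t, p)``
    two-sided; two zero-variance samples with equal means give p = 1 by
    convention.
    """
    if isinstance(a, AlignedGroup):
        if descriptor is None:
            raise ValueError("descriptor required for AlignedGroup inputs")
        a = percent_change(a, descriptor)["percent_change"].to_numpy()
        b = percent_change(b, descriptor)["percent_change"].to_numpy()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
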