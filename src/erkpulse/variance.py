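"""Variance-based measures of ERK pulse levels.

Two complementary statistics quantify pulsing without counting discrete
peaks:

* **Instantaneous variance** — the variance of FRET/CFP across all cells at
  one time point; a population-level pulse measure (an increase indicates
  higher variability of ERK activity at that moment).
* **Moving variance** — per cell, the variance of FRET/CFP in overlapping
  50-min windows: short enough for the mean to be considered fixed within
  the window, long enough to accommodate a typical ~0.25 h pulse. Zero
  corresponds to a signal without pulses or fluctuations; larger values mean
  more pulsing. The variance captures both pulse amplitude and count, giving
  a continuous per-cell "pulse level".

Sample variance (denominator n-1) is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .traces import Trace

__all__ = [
    "WindowSeries",
    "PopulationVarianceSeries",
    "instantaneous_variance",
    "moving_variance",
    "pulse_level_score",
]


@dataclass
class WindowSeries:
    """Per-cell moving-window variance and means of ERK (and reporter)."""

    cell_id: str
    window_centers_h: np.ndarray
    erk_moving_variance: np.ndarray
    erk_moving_mean: np.ndarray
    reporter_moving_mean: np.ndarray | None
    window_min: float

    def __len__(self) -> int:
        return self.window_centers_h.size


@dataclass
class PopulationVarianceSeries:
    """Cross-population (instantaneous) variance of the ratio over time."""

    times_h: np.ndarray
    variance: np.ndarray
    n_cells: np.ndarray


def instantaneous_variance(traces, timepoints=None, atol_h: float = 1e-6) -> PopulationVarianceSeries:
    """Variance of the ratio across cells at each time point.

    Time points observed by fewer than 2 cells are omitted. If ``timepoints``
    is not given, the union of all trace time grids is used (matched within
    ``atol_h``).
    """
    traces = list(traces)
    if timepoints is None:
        if not traces:
            warnings.warn("no traces given; empty series", stacklevel=2)
            return PopulationVarianceSeries(np.empty(0), np.empty(0), np.empty(0, dtype=int))
        allt = np.concatenate([tr.times_h for tr in traces])
        timepoints = np.unique(np.round(allt / atol_h) * atol_h)
    timepoints = np.asarray(timepoints, dtype=float)

    times_out, var_out, n_out = [], [], []
    for t in timepoints:
        vals = []
        for tr in traces:
            i = np.searchsorted(tr.times_h, t)
            for j in (i - 1, i):
                if 0 <= j < tr.times_h.size and abs(tr.times_h[j] - t) <= atol_h:
                    vals.append(tr.ratio[j])
                    break
        if len(vals) >= 2:
            v = np.asarray(vals)
            times_out.append(t)
            var_out.append(np.var(v - v[0], ddof=1))  # shift-invariant, exact for ties
            n_out.append(len(vals))
    if not times_out:
        warnings.warn("no timepoint observed by >= 2 cells; empty series", stacklevel=2)
    return PopulationVarianceSeries(
        np.asarray(times_out), np.asarray(var_out), np.asarray(n_out, dtype=int)
    )


def moving_variance(trace: Trace, window_min: float = 50.0, min_samples: int = 3) -> WindowSeries:
    """Overlapping moving-window variance (and means) of one trace.

    Windows are defined on time — length ``window_min`` minutes, centered on
    each sample, stepped by one sampling interval — so 5- and 15-min data
    share one definition. Partial windows at the trace edges are dropped;
    windows retaining fewer than ``min_samples`` samples are skipped.
    """
    half_h = window_min / 120.0
    t, y = trace.times_h, trace.ratio
    if trace.span_h < window_min / 60.0:
        raise ValueError(
            f"trace {trace.cell_id!r}: span {trace.span_h * 60:.0f} min shorter than one "
            f"{window_min:.0f}-min window"
        )
    rep = trace.reporter
    eps = 1e-9

    centers, vs, ms, rs = [], [], [], []
    for tc in t:
        if tc - t[0] < half_h - eps or t[-1] - tc < half_h - eps:
            continue
        lo = np.searchsorted(t, tc - half_h - eps, side="left")
        hi = np.searchsorted(t, tc + half_h + eps, side="right")
        w = y[lo:hi]
        w = w[np.isfinite(w)]
        if w.size < min_samples:
            continue
        centers.append(tc)
        # shift by the first sample: shift-invariant, and exactly 0 for
        # constant windows even when the level is not binary-representable
        w0 = w - w[0]
        vs.append(np.var(w0, ddof=1))
        ms.append(w[0] + np.mean(w0))
        if rep is not None:
            rw = rep[lo:hi]
            rs.append(np.mean(rw[np.isfinite(rw)]))
    return WindowSeries(
        cell_id=trace.cell_id,
        window_centers_h=np.asarray(centers),
        erk_moving_variance=np.asarray(vs),
        erk_moving_mean=np.asarray(ms),
        reporter_moving_mean=np.asarray(rs) if rep is not None else None,
        window_min=float(window_min),
    )


def pulse_level_score(ws: WindowSeries) -> float:
    """Per-cell pulse level: time-average of the moving variance."""
    if len(ws) == 0:
        raise ValueError(f"empty window series for cell {ws.cell_id!r}")
    return float(np.mean(ws.erk_moving_variance))
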