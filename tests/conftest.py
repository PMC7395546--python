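"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from erkpulse.traces import Trace


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the library implementations
# ---------------------------------------------------------------------------

def oracle_peaks(y, min_prominence: float, distance: int) -> list[int]:
    """Exhaustive peak scan: local maxima (plateau tops count once, at their
    midpoint), greedy distance selection (highest peak first), then a
    topographic-prominence filter.

    Prominence of peak i: extend left/right until a strictly higher sample or
    the signal edge, take the minimum on each side; prominence is the peak
    height above the higher of the two minima.
    """
    y = list(map(float, y))
    n = len(y)
    cands = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:  # falls off on the right: a peak
                cands.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    kept = set(cands)
    for i in sorted(cands, key=lambda j: (y[j], j), reverse=True):
        if i not in kept:
            continue
        for j in list(kept):
            if j != i and abs(j - i) < distance:
                kept.discard(j)

    out = []
    for i in sorted(kept):
        jmin = y[i]
        j = i - 1
        while j >= 0 and y[j] <= y[i]:
            jmin = min(jmin, y[j])
            j -= 1
        left_base = jmin
        jmin = y[i]
        j = i + 1
        while j < n and y[j] <= y[i]:
            jmin = min(jmin, y[j])
            j += 1
        right_base = jmin
        if y[i] - max(left_base, right_base) >= min_prominence:
            out.append(i)
    return out


def oracle_moving_variance(times_h, y, window_min: float):
    """Naive per-window recomputation: for every sample time far enough from
    both trace ends, gather samples within half a window and compute the
    two-pass sample variance with plain Python sums."""
    half = window_min / 120.0
    eps = 1e-9
    centers, variances = [], []
    for tc in times_h:
        if tc - times_h[0] < half - eps or times_h[-1] - tc < half - eps:
            continue
        vals = [float(v) for t, v in zip(times_h, y) if abs(t - tc) <= half + eps]
        if len(vals) < 3:
            continue
        m = sum(vals) / len(vals)
        var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        centers.append(float(tc))
        variances.append(var)
    return np.asarray(centers), np.asarray(variances)


@pytest.fixture
def make_trace():
    """Factory for uniform-grid traces with a given ratio vector."""

    def _make(ratio, dt_min: float = 5.0, cell_id: str = "c0", reporter=None, **kw) -> Trace:
        ratio = np.asarray(ratio, dtype=float)
        times = np.arange(ratio.size) * dt_min / 60.0
        return Trace(cell_id=cell_id, times_h=times, ratio=ratio, reporter=reporter, **kw)

    return _make
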