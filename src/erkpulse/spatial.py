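"""Radial distribution function (RDF) analysis of marked cell positions.

The RDF g(r) compares the number N(r, dr) of cells found in rings of radius
r and width dr around reference cells with the count N_ref(r, dr) obtained
for uniformly random points in the same field of interest:

    g(r) = N(r, dr) / N_ref(r, dr)

Under complete spatial randomness (CSR) g(r) = 1 in expectation. Significance
is assessed against a Monte-Carlo envelope: the 2.5th/97.5th percentiles of
g over repeated CSR realizations in the same field at the same point count.
A single population is *clustered* (above the envelope) or *dispersed*
(below); for two marked populations, rings are drawn around one group and
cells of the other group are counted, and the populations are *grouped*
(above) or *segregated* (below).

Edge effects are handled by construction of the field of interest — only
regions where cells were actually observed are considered — rather than by
analytic edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy.spatial.distance import cdist, pdist
from shapely.geometry import box

__all__ = [
    "FieldOfInterest",
    "FieldError",
    "RDFResult",
    "build_field_of_interest",
    "default_r_grid",
    "rdf",
    "cross_rdf",
    "null_envelope",
    "attach_envelope",
    "classify",
    "rdf_analysis",
]


class FieldError(ValueError):
    """Degenerate or invalid field of interest."""


@dataclass(frozen=True)
class FieldOfInterest:
    """Region of space where cells were observed, as a shapely geometry."""

    geometry: object  # shapely Polygon / MultiPolygon

    @classmethod
    def rectangle(cls, width_um: float, height_um: float) -> "FieldOfInterest":
        if width_um <= 0 or height_um <= 0:
            raise FieldError("rectangle sides must be positive")
        return cls(box(0.0, 0.0, float(width_um), float(height_um)))

    @property
    def area_um2(self) -> float:
        return float(self.geometry.area)

    def contains(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.geometry, np.asarray(x, float), np.asarray(y, float))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the field, by rejection from the bounding box."""
        if self.area_um2 <= 0:
            raise FieldError("field of interest has zero area")
        minx, miny, maxx, maxy = self.geometry.bounds
        out = np.empty((n, 2), dtype=float)
        filled = 0
        frac = self.area_um2 / ((maxx - minx) * (maxy - miny))
        while filled < n:
            m = max(64, int(1.5 * (n - filled) / max(frac, 1e-6)))
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            keep = shapely.contains_xy(self.geometry, xs, ys)
            take = min(int(keep.sum()), n - filled)
            out[filled : filled + take, 0] = xs[keep][:take]
            out[filled : filled + take, 1] = ys[keep][:take]
            filled += take
        return out


def build_field_of_interest(points, dilation_radius_um: float) -> FieldOfInterest:
    """Field of interest as the union of discs around observed cells.

    Requires at least 3 points; the dilation radius sets how far beyond the
    observed cells the field extends (as radius -> 0, area -> 0).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise FieldError("need at least 3 points to build a field of interest")
    discs = shapely.buffer(shapely.points(pts), float(dilation_radius_um))
    return FieldOfInterest(shapely.union_all(discs))


@dataclass(frozen=True)
class RDFResult:
    """RDF g(r) on a ring grid, optionally with a null envelope and labels."""

    r_centers_um: np.ndarray
    dr_um: float
    g: np.ndarray
    counts: np.ndarray
    ref_counts: np.ndarray
    mode: str = "single"  # single | cross
    null_mean: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_null_realizations: int = 0
    classification: list | None = None


def default_r_grid(r_min: float = 5.0, r_max: float = 150.0, dr: float = 10.0) -> np.ndarray:
    """Ring centers r_min, r_min+dr, ... below r_max (default 5..145 um)."""
    return np.arange(r_min, r_max, dr, dtype=float)


def _ring_counts(ref_xy, target_xy, r_centers, dr, same_set: bool) -> np.ndarray:
    """Total counts per half-open ring [r - dr/2, r + dr/2).

    For a single population each unordered pair contributes twice (once
    around each member). In cross mode each (reference, target) pair
    contributes once.
    """
    r_centers = np.asarray(r_centers, dtype=float)
    lo = r_centers - dr / 2.0
    hi = r_centers + dr / 2.0
    if same_set:
        d = pdist(np.asarray(ref_xy, dtype=float))
        weight = 2
    else:
        d = cdist(np.asarray(ref_xy, dtype=float), np.asarray(target_xy, dtype=float)).ravel()
        weight = 1
    d.sort()
    # half-open rings: count(d < hi) - count(d < lo)
    return weight * (np.searchsorted(d, hi, side="left") - np.searchsorted(d, lo, side="left")).astype(float)


def _as_xy(points) -> np.ndarray:
    if hasattr(points, "columns"):
        return points[["x_um", "y_um"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(points, dtype=float))


def rdf(
    points,
    field: FieldOfInterest,
    r_centers=None,
    dr_um: float = 10.0,
    n_ref_realizations: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RDFResult:
    """Single-population RDF of a point pattern inside a field of interest.

    N_ref is averaged over ``n_ref_realizations`` CSR realizations at the
    same point count to reduce its own Monte-Carlo noise. Radii where
    N_ref = 0 are returned as NaN rather than divided.
    """
    xy = _as_xy(points)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 points for an RDF")
    if r_centers is None:
        r_centers = default_r_grid(dr=dr_um)
    r_centers = np.asarray(r_centers, dtype=float)
    if np.any(r_centers <= 0):
        raise ValueError("ring radii must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng

    counts = _ring_counts(xy, xy, r_centers, dr_um, same_set=True)
    ref = np.zeros_like(counts)
    for _ in range(n_ref_realizations):
        rnd = field.sample_uniform(xy.shape[0], rng)
        ref += _ring_counts(rnd, rnd, r_centers, dr_um, same_set=True)
    ref /= n_ref_realizations
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ref > 0, counts / ref, np.nan)
    return RDFResult(r_centers, float(dr_um), g, counts, ref, mode="single")


def cross_rdf(
    reference_points,
    target_points,
    field: FieldOfInterest,
    r_centers=None,
    dr_um: float = 10.0,
    n_ref_realizations: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RDFResult:
    """Cross-population RDF: rings around reference cells, targets counted.

    N_ref replaces the targets by CSR points at the same count, keeping the
    reference cells fixed.
    """
    ref_xy = _as_xy(reference_points)
    tgt_xy = _as_xy(target_points)
    if ref_xy.shape[0] < 1 or tgt_xy.shape[0] < 1:
        raise ValueError("both point groups must be nonempty")
    if r_centers is None:
        r_centers = default_r_grid(dr=dr_um)
    r_centers = np.asarray(r_centers, dtype=float)
    rng = np.random.default_rng(seed) if rng is None else rng

    counts = _ring_counts(ref_xy, tgt_xy, r_centers, dr_um, same_set=False)
    ref = np.zeros_like(counts)
    for _ in range(n_ref_realizations):
        rnd = field.sample_uniform(tgt_xy.shape[0], rng)
        ref += _ring_counts(ref_xy, rnd, r_centers, dr_um, same_set=False)
    ref /= n_ref_realizations
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ref > 0, counts / ref, np.nan)
    return RDFResult(r_centers, float(dr_um), g, counts, ref, mode="cross")


def null_envelope(
    field: FieldOfInterest,
    n_points: int,
    r_centers=None,
    dr_um: float = 10.0,
    n_realizations: int = 50,
    seed: int | None = None,
    n_ref_realizations: int = 20,
    reference_points=None,
):
    """Monte-Carlo null envelope for g(r): mean and 95% percentile bounds.

    Each realization computes g for a fresh CSR pattern (single mode), or —
    when ``reference_points`` is given — for CSR targets around the fixed
    reference cells (cross mode). Returns (null_mean, ci_low, ci_high).

    The bounds are the rank-based simulation envelope [min, max] of the
    realizations: with m simulations a new null draw exceeds it with
    probability 2/(m+1) pointwise (3.9% at m=50, the conservative side of a
    nominal 95% interval). Interpolated 2.5/97.5 percentiles of 50 draws
    would cover only ~91% and systematically over-flag CSR patterns.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 null realizations")
    if field.area_um2 <= 0:
        raise FieldError("field of interest has zero area")
    if r_centers is None:
        r_centers = default_r_grid(dr=dr_um)
    r_centers = np.asarray(r_centers, dtype=float)
    rng = np.random.default_rng(seed)

    gs = np.empty((n_realizations, r_centers.size))
    for i in range(n_realizations):
        if reference_points is None:
            pts = field.sample_uniform(n_points, rng)
            res = rdf(pts, field, r_centers, dr_um, n_ref_realizations, rng=rng)
        else:
            tgt = field.sample_uniform(n_points, rng)
            res = cross_rdf(
                reference_points, tgt, field, r_centers, dr_um, n_ref_realizations, rng=rng
            )
        gs[i] = res.g
    null_mean = np.nanmean(gs, axis=0)
    ci_low = np.nanmin(gs, axis=0)
    ci_high = np.nanmax(gs, axis=0)
    return null_mean, ci_low, ci_high


def attach_envelope(result: RDFResult, null_mean, ci_low, ci_high, n_realizations: int) -> RDFResult:
    return replace(
        result,
        null_mean=np.asarray(null_mean, float),
        ci_low=np.asarray(ci_low, float),
        ci_high=np.asarray(ci_high, float),
        n_null_realizations=int(n_realizations),
    )


def classify(result: RDFResult, mode: str | None = None) -> list:
    """Per-radius classification of g(r) against the null envelope.

    Single population: above the 95% CI -> ``clustered``, below ->
    ``dispersed``. Cross population: below -> ``segregated``, above ->
    ``grouped``. Inside the envelope -> ``consistent_with_null``; radii with
    undefined g -> ``undefined``.
    """
    mode = result.mode if mode is None else mode
    if mode not in ("single", "cross"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != result.mode:
        raise ValueError(f"mode {mode!r} does not match RDF computed in {result.mode!r} mode")
    if result.ci_low is None or result.ci_high is None:
        raise ValueError("RDF result carries no null envelope")
    above, below = ("clustered", "dispersed") if mode == "single" else ("grouped", "segregated")
    labels = []
    for g, lo, hi in zip(result.g, result.ci_low, result.ci_high):
        if not np.isfinite(g) or not np.isfinite(lo) or not np.isfinite(hi):
            labels.append("undefined")
        elif g > hi:
            labels.append(above)
        elif g < lo:
            labels.append(below)
        else:
            labels.append("consistent_with_null")
    return labels


def rdf_analysis(
    points,
    field: FieldOfInterest,
    reference_points=None,
    r_centers=None,
    dr_um: float = 10.0,
    n_null_realizations: int = 50,
    n_ref_realizations: int = 20,
    seed: int | None = None,
) -> RDFResult:
    """RDF + null envelope + classification in one call.

    ``points`` is the (single or target) population; pass ``reference_points``
    for cross-population analysis.
    """
    if reference_points is None:
        res = rdf(points, field, r_centers, dr_um, n_ref_realizations, seed=seed)
    else:
        res = cross_rdf(
            reference_points, points, field, r_centers, dr_um, n_ref_realizations, seed=seed
        )
    n_tgt = _as_xy(points).shape[0]
    env = null_envelope(
        field,
        n_tgt,
        res.r_centers_um,
        dr_um,
        n_null_realizations,
        seed=None if seed is None else seed + 1,
        n_ref_realizations=n_ref_realizations,
        reference_points=reference_points,
    )
    res = attach_envelope(res, *env, n_realizations=n_null_realizations)
    return replace(res, classification=classify(res))
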