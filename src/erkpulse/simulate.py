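"""Synthetic ERK traces and marked spatial point patterns.

Traces emulate the statistical structure of live-imaged keratinocyte ERK
activity: a basal FRET/CFP level near 1.0-1.2, stochastic activity pulses
with exponentially distributed interpulse intervals (mean ~1.5 h), pulse
duration ~0.25 h, 5-min sampling for up to 24 h, and Gaussian measurement
noise of much smaller amplitude than the pulses. A differentiation mode
couples pulse shutdown to the onset of a (Involucrin-like) reporter signal.

Spatial patterns emulate basal-layer cell maps: complete spatial randomness
(CSR) or a Thomas cluster process whose marks can follow cluster membership,
mimicking spatially segregated low- and high-pulsing populations.

Pulses are phenomenological events (no mechanistic MAPK network model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import FieldOfInterest, FieldError
from .traces import Trace

__all__ = [
    "SimConfig",
    "SpatialSimConfig",
    "SpatialPattern",
    "ConfigError",
    "draw_pulse_times",
    "simulate_trace",
    "simulate_cohort",
    "simulate_spatial_pattern",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated single-cell ERK trace.

    ``pulse_rate_per_h`` is the inverse of the mean interpulse interval
    (default 1/1.52 h^-1). The pulse waveform is a raised-cosine bump of
    full width ``pulse_duration_h`` and height ``pulse_amplitude`` added to
    ``basal_level``; overlapping pulses sum. With
    ``reporter_onset_model="coupled_to_pulse_shutdown"``, pulsing stops at
    ``shutdown_time_h`` and the reporter rises as a saturating ramp
    thereafter, emulating pulse down-regulation coincident with
    differentiation-reporter onset.
    """

    seed: int = 0
    sampling_interval_min: float = 5.0
    duration_h: float = 24.0
    pulse_rate_per_h: float = 1.0 / 1.52
    pulse_duration_h: float = 0.25
    pulse_amplitude: float = 0.25
    basal_level: float = 1.1
    noise_sd: float = 0.02
    reporter_onset_model: str = "none"  # none | coupled_to_pulse_shutdown
    shutdown_time_h: float | None = None
    reporter_max: float = 100.0
    reporter_tau_h: float = 2.0
    label: str = ""

    def validate(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ConfigError("sampling_interval_min must be positive")
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be positive")
        if self.pulse_rate_per_h < 0:
            raise ConfigError("pulse_rate_per_h must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.pulse_duration_h <= 0:
            raise ConfigError("pulse_duration_h must be positive")
        if self.pulse_rate_per_h > 0 and self.pulse_duration_h >= 1.0 / self.pulse_rate_per_h:
            raise ConfigError("pulse_duration_h must be below the mean interpulse interval")
        if self.reporter_onset_model not in ("none", "coupled_to_pulse_shutdown"):
            raise ConfigError(f"unknown reporter_onset_model {self.reporter_onset_model!r}")
        if self.reporter_onset_model == "coupled_to_pulse_shutdown" and self.shutdown_time_h is None:
            raise ConfigError("shutdown_time_h required for coupled_to_pulse_shutdown")


def draw_pulse_times(
    rng: np.random.Generator, rate_per_h: float, duration_h: float
) -> np.ndarray:
    """Pulse event times on [0, duration): renewal process with Exp gaps.

    Successive gaps are iid exponential with mean 1/rate, so event times
    form a homogeneous Poisson process and interpulse intervals follow an
    exponential distribution at the configured rate.
    """
    if rate_per_h <= 0:
        return np.empty(0)
    times: list[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_h)
        if t >= duration_h:
            break
        times.append(t)
    return np.asarray(times)


def _raised_cosine(times_h: np.ndarray, centers_h: np.ndarray, duration_h: float, amplitude: float) -> np.ndarray:
    """Sum of raised-cosine bumps: smooth, compact support of full width duration_h."""
    out = np.zeros_like(times_h)
    half = duration_h / 2.0
    for c in centers_h:
        m = np.abs(times_h - c) < half
        if m.any():
            out[m] += amplitude * 0.5 * (1.0 + np.cos(np.pi * (times_h[m] - c) / half))
    return out


def simulate_trace(config: SimConfig, rng: np.random.Generator | None = None, cell_id: str = "sim_0000") -> Trace:
    """Simulate one ERK trace on a uniform time grid. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    dt_h = config.sampling_interval_min / 60.0
    n = int(np.floor(config.duration_h / dt_h)) + 1
    times = np.arange(n) * dt_h

    pulse_window_h = config.duration_h
    if config.reporter_onset_model == "coupled_to_pulse_shutdown":
        pulse_window_h = min(config.duration_h, float(config.shutdown_time_h))
    events = draw_pulse_times(rng, config.pulse_rate_per_h, pulse_window_h)

    ratio = np.full(n, config.basal_level, dtype=float)
    ratio += _raised_cosine(times, events, config.pulse_duration_h, config.pulse_amplitude)
    if config.noise_sd > 0:
        ratio += rng.normal(0.0, config.noise_sd, n)

    reporter = None
    if config.reporter_onset_model == "coupled_to_pulse_shutdown":
        ts = float(config.shutdown_time_h)
        reporter = np.zeros(n)
        after = times > ts
        reporter[after] = config.reporter_max * (1.0 - np.exp(-(times[after] - ts) / config.reporter_tau_h))

    return Trace(
        cell_id=cell_id,
        times_h=times,
        ratio=ratio,
        reporter=reporter,
        label=config.label,
    )


def simulate_cohort(configs, n_per_config: int) -> list[Trace]:
    """Independent traces per config, with sub-seeds derived from the master seed.

    Each trace gets its own generator spawned from ``(config.seed, index)``
    via :class:`numpy.random.SeedSequence`, so streams are uncorrelated and
    the whole cohort is reproducible from the config seeds.
    """
    configs = list(configs)
    if not configs:
        raise ConfigError("empty config list")
    if n_per_config < 1:
        raise ConfigError("n_per_config must be >= 1")
    traces: list[Trace] = []
    for c in configs:
        c.validate()
        ss = np.random.SeedSequence(c.seed)
        children = ss.spawn(n_per_config)
        label = c.label or "cohort"
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            traces.append(simulate_trace(c, rng=rng, cell_id=f"{label}_{i:04d}"))
    return traces


@dataclass(frozen=True)
class SpatialSimConfig:
    """Parameters of one simulated marked point pattern.

    ``process="csr"`` scatters points uniformly in the field;
    ``"thomas_cluster"`` places Gaussian clusters of spread ``cluster_sd_um``
    around uniform parents (intensity ``parent_intensity_per_um2``).
    Marks ("low" / "high" pulse class) are assigned independently with
    probability ``mark_fraction_low``, or by cluster membership
    (``"clustered_low_pulse"``: low-pulsing cells are the cluster offspring,
    high-pulsing cells scatter uniformly outside an exclusion zone of
    ``2 * cluster_sd_um`` around cluster centers), emulating spatially
    segregated pulse classes in the basal layer.
    """

    seed: int = 0
    n_points: int = 1000
    field: FieldOfInterest = field(
        default_factory=lambda: FieldOfInterest.rectangle(1000.0, 1000.0)
    )
    process: str = "csr"  # csr | thomas_cluster
    parent_intensity_per_um2: float = 3.5e-5
    cluster_sd_um: float = 25.0
    mark_model: str = "independent"  # independent | clustered_low_pulse
    mark_fraction_low: float = 0.5

    def validate(self) -> None:
        if self.n_points <= 0:
            raise ConfigError("n_points must be positive")
        if self.field.area_um2 <= 0:
            raise FieldError("field of interest has zero area")
        if self.process not in ("csr", "thomas_cluster"):
            raise ConfigError(f"unknown process {self.process!r}")
        if self.mark_model not in ("independent", "clustered_low_pulse"):
            raise ConfigError(f"unknown mark_model {self.mark_model!r}")
        if self.process == "thomas_cluster":
            if self.parent_intensity_per_um2 <= 0 or self.cluster_sd_um <= 0:
                raise ConfigError("thomas_cluster needs positive parent intensity and cluster sd")
        if self.mark_model == "clustered_low_pulse" and self.process != "thomas_cluster":
            raise ConfigError("clustered_low_pulse marks require the thomas_cluster process")
        if not 0.0 <= self.mark_fraction_low <= 1.0:
            raise ConfigError("mark_fraction_low must lie in [0, 1]")


@dataclass(frozen=True)
class SpatialPattern:
    points: pd.DataFrame  # columns x_um, y_um, mark
    field: FieldOfInterest

    def group(self, mark: str) -> np.ndarray:
        sel = self.points[self.points["mark"] == mark]
        return sel[["x_um", "y_um"]].to_numpy(dtype=float)


def _thomas_offspring(
    parents: np.ndarray, n: int, sd: float, fieldo: FieldOfInterest, rng: np.random.Generator
):
    """n offspring around the given parents, rejected to the field interior."""
    xy = np.empty((n, 2))
    parent_of = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        m = max(64, 2 * (n - filled))
        idx = rng.integers(0, parents.shape[0], m)
        cand = parents[idx] + rng.normal(0.0, sd, (m, 2))
        keep = fieldo.contains(cand[:, 0], cand[:, 1])
        take = min(int(keep.sum()), n - filled)
        xy[filled : filled + take] = cand[keep][:take]
        parent_of[filled : filled + take] = idx[keep][:take]
        filled += take
    return xy, parent_of


def _uniform_excluding(
    fieldo: FieldOfInterest,
    n: int,
    centers: np.ndarray,
    exclusion_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """n uniform points in the field at least exclusion_um from every center."""
    out = np.empty((n, 2))
    filled = 0
    r2 = exclusion_um**2
    stalled = 0
    while filled < n:
        if stalled > 200:
            raise ConfigError("exclusion zones cover (nearly) the whole field")
        cand = fieldo.sample_uniform(max(64, 2 * (n - filled)), rng)
        d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        keep = d2 >= r2
        take = min(int(keep.sum()), n - filled)
        stalled = stalled + 1 if take == 0 else 0
        out[filled : filled + take] = cand[keep][:take]
        filled += take
    return out


def simulate_spatial_pattern(config: SpatialSimConfig) -> SpatialPattern:
    """Simulate a marked point pattern in a field of interest; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_points

    if config.process == "csr":
        xy = config.field.sample_uniform(n, rng)
        parent_mark = None
        parent_of = None
    else:
        n_parents = max(1, int(rng.poisson(config.parent_intensity_per_um2 * config.field.area_um2)))
        parents = config.field.sample_uniform(n_parents, rng)
        if config.mark_model == "clustered_low_pulse":
            # low-pulsing cells form the clusters; high-pulsing cells fill the
            # complement, kept out of a 2-sd exclusion zone around cluster centers
            n_low = int(round(config.mark_fraction_low * n))
            xy_low, _ = _thomas_offspring(parents, n_low, config.cluster_sd_um, config.field, rng)
            xy_high = _uniform_excluding(
                config.field, n - n_low, parents, 2.0 * config.cluster_sd_um, rng
            )
            pts = pd.DataFrame(
                {
                    "x_um": np.concatenate([xy_low[:, 0], xy_high[:, 0]]),
                    "y_um": np.concatenate([xy_low[:, 1], xy_high[:, 1]]),
                    "mark": ["low"] * n_low + ["high"] * (n - n_low),
                }
            )
            return SpatialPattern(points=pts, field=config.field)
        xy, parent_of = _thomas_offspring(parents, n, config.cluster_sd_um, config.field, rng)

    marks = np.where(rng.random(n) < config.mark_fraction_low, "low", "high")
    pts = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "mark": marks})
    return SpatialPattern(points=pts, field=config.field)


def write_pattern(pattern: SpatialPattern, points_path, boundary_path=None) -> None:
    """Write a pattern as CSV (x_um, y_um, mark) plus a GeoJSON boundary polygon."""
    pattern.points.to_csv(points_path, index=False)
    if boundary_path is not None:
        import json

        import shapely.geometry

        with open(boundary_path, "w") as fh:
            json.dump(shapely.geometry.mapping(pattern.field.geometry), fh)
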