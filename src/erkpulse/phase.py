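"""Phase diagrams of ERK pulse level vs. differentiation-reporter level.

Each cell contributes a trajectory in the plane spanned by the reporter
(e.g. Involucrin) moving mean (x) and the ERK moving variance — or moving
mean — (y), both computed on 50-min windows; only traces longer than 90 min
enter. The plane is divided into regular blocks; consecutive-point
displacements are assigned to the block containing their start point and
averaged into a per-block mean arrow: the direction in which cells in that
region of the plane move over time.

Arrow components are rescaled by the global axis maxima,
x' = x / max(reporter mean) and y' = y / max(ERK variance), and converted to
normalized transition probabilities

    r_x = x' / (|x'| + |y'|),   r_y = y' / (|x'| + |y'|),

so that |r_x| + |r_y| = 1 for every populated block. |r_x| is the
probability of transitioning toward neighboring blocks along the reporter
axis (|r_y| along the ERK axis); a negative sign indicates a transition
toward decreasing values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .traces import Trace, filter_min_duration
from .variance import moving_variance

__all__ = [
    "Trajectory",
    "PhaseDiagram",
    "MissingChannelError",
    "build_trajectories",
    "bin_and_average",
    "normalize_and_transition",
    "plot_phase_diagram",
]


class MissingChannelError(ValueError):
    """A required signal channel is absent from a trace."""


@dataclass
class Trajectory:
    """One cell's time-ordered path in the (reporter mean, ERK metric) plane."""

    cell_id: str
    x: np.ndarray  # reporter moving mean
    y: np.ndarray  # ERK moving variance or moving mean
    metric_kind: str  # variance | mean

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size or self.x.size < 2:
            raise ValueError("trajectory needs >= 2 paired points")

    @property
    def n_segments(self) -> int:
        return self.x.size - 1


@dataclass(frozen=True)
class PhaseDiagram:
    """Binned vector field over the (reporter mean, ERK metric) plane.

    ``arrow_x``/``arrow_y`` hold each block's mean displacement (NaN where
    no segment starts in the block); after normalization, ``r_x``/``r_y``
    hold the signed transition probabilities.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # segments per block, shape (nx, ny)
    arrow_x: np.ndarray
    arrow_y: np.ndarray
    x_max: float  # global max of the raw reporter moving mean
    y_max: float  # global max of the raw ERK metric
    metric_kind: str
    x_prime: np.ndarray | None = None
    y_prime: np.ndarray | None = None
    r_x: np.ndarray | None = None
    r_y: np.ndarray | None = None

    @property
    def n_blocks(self) -> tuple[int, int]:
        return self.x_edges.size - 1, self.y_edges.size - 1

    @property
    def total_segments(self) -> int:
        return int(self.counts.sum())


def build_trajectories(
    traces,
    window_min: float = 50.0,
    metric_kind: str = "variance",
    min_duration_min: float = 90.0,
) -> list[Trajectory]:
    """Per-cell (reporter moving mean, ERK metric) trajectories.

    Traces must carry the reporter channel; only traces spanning strictly
    more than ``min_duration_min`` are analyzed.
    """
    if metric_kind not in ("variance", "mean"):
        raise ValueError(f"unknown metric_kind {metric_kind!r}")
    kept = filter_min_duration(list(traces), min_duration_min)
    trajs: list[Trajectory] = []
    for tr in kept:
        if tr.reporter is None:
            raise MissingChannelError(
                f"trace {tr.cell_id!r} has no 'reporter' channel required for phase diagrams"
            )
        ws = moving_variance(tr, window_min=window_min)
        if len(ws) < 2:
            continue
        y = ws.erk_moving_variance if metric_kind == "variance" else ws.erk_moving_mean
        trajs.append(
            Trajectory(cell_id=tr.cell_id, x=ws.reporter_moving_mean, y=y, metric_kind=metric_kind)
        )
    return trajs


def _block_index(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open blocks [e_i, e_{i+1}), closed at the global maximum."""
    idx = np.searchsorted(edges, v, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def bin_and_average(trajs, n_blocks_x: int = 10, n_blocks_y: int = 10) -> PhaseDiagram:
    """Divide the plane into regular blocks and average trajectory segments.

    Each consecutive-point displacement is assigned to the block containing
    its start point; the per-block arrow is the mean displacement of the
    segments starting there. The grid spans [0, max] on each raw axis.
    """
    trajs = list(trajs)
    if not trajs or sum(t.n_segments for t in trajs) < 1:
        raise ValueError("need at least one trajectory segment")
    kinds = {t.metric_kind for t in trajs}
    if len(kinds) != 1:
        raise ValueError("mixed metric kinds in one diagram")

    all_x = np.concatenate([t.x for t in trajs])
    all_y = np.concatenate([t.y for t in trajs])
    x_max = float(np.max(all_x))
    y_max = float(np.max(all_y))
    if x_max <= 0 or y_max <= 0:
        raise ValueError("degenerate plane extent: zero range on an axis")

    x_edges = np.linspace(0.0, x_max, n_blocks_x + 1)
    y_edges = np.linspace(0.0, y_max, n_blocks_y + 1)
    counts = np.zeros((n_blocks_x, n_blocks_y), dtype=int)
    sum_dx = np.zeros((n_blocks_x, n_blocks_y))
    sum_dy = np.zeros((n_blocks_x, n_blocks_y))

    for t in trajs:
        ix = _block_index(t.x[:-1], x_edges)
        iy = _block_index(t.y[:-1], y_edges)
        dx = np.diff(t.x)
        dy = np.diff(t.y)
        np.add.at(counts, (ix, iy), 1)
        np.add.at(sum_dx, (ix, iy), dx)
        np.add.at(sum_dy, (ix, iy), dy)

    with np.errstate(invalid="ignore"):
        arrow_x = np.where(counts > 0, sum_dx / np.maximum(counts, 1), np.nan)
        arrow_y = np.where(counts > 0, sum_dy / np.maximum(counts, 1), np.nan)
    return PhaseDiagram(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        arrow_x=arrow_x,
        arrow_y=arrow_y,
        x_max=x_max,
        y_max=y_max,
        metric_kind=trajs[0].metric_kind,
    )


def normalize_and_transition(pd_: PhaseDiagram) -> PhaseDiagram:
    """Rescale arrows by the global axis maxima and derive r_x, r_y.

    Blocks with no segments or an exactly zero arrow get NaN probabilities
    (flagged absent). Raises if no block carries a nonzero arrow.
    """
    xp = pd_.arrow_x / pd_.x_max
    yp = pd_.arrow_y / pd_.y_max
    denom = np.abs(xp) + np.abs(yp)
    ok = np.isfinite(denom) & (denom > 0)
    if not ok.any():
        raise ValueError("all arrows are zero or empty; nothing to normalize")
    r_x = np.where(ok, xp / np.where(ok, denom, 1.0), np.nan)
    r_y = np.where(ok, yp / np.where(ok, denom, 1.0), np.nan)
    return replace(pd_, x_prime=xp, y_prime=yp, r_x=r_x, r_y=r_y)


def plot_phase_diagram(pd_: PhaseDiagram, ax=None, min_count: int = 1):
    """Quiver plot of the block arrows (blocks with < min_count segments hidden)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xc = 0.5 * (pd_.x_edges[:-1] + pd_.x_edges[1:])
    yc = 0.5 * (pd_.y_edges[:-1] + pd_.y_edges[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    show = pd_.counts >= min_count
    ax.quiver(X[show], Y[show], pd_.arrow_x[show], pd_.arrow_y[show], angles="xy")
    ax.set_xlabel("reporter moving mean")
    ylabel = "ERK moving variance" if pd_.metric_kind == "variance" else "ERK moving mean"
    ax.set_ylabel(ylabel)
    return ax
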