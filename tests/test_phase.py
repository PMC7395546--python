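"""Phase-diagram binning, normalization identities, and flow recovery."""

import numpy as np
import pytest

from erkpulse.phase import (
    MissingChannelError,
    PhaseDiagram,
    Trajectory,
    bin_and_average,
    build_trajectories,
    normalize_and_transition,
)
from erkpulse.simulate import SimConfig, simulate_cohort


def _diagram_with_arrow(dx, dy, x_max=1.0, y_max=1.0):
    arrow_x = np.full((1, 1), dx)
    arrow_y = np.full((1, 1), dy)
    return PhaseDiagram(
        x_edges=np.array([0.0, x_max]),
        y_edges=np.array([0.0, y_max]),
        counts=np.ones((1, 1), dtype=int),
        arrow_x=arrow_x,
        arrow_y=arrow_y,
        x_max=x_max,
        y_max=y_max,
        metric_kind="variance",
    )


def test_transition_probabilities_hand_computed():
    d = normalize_and_transition(_diagram_with_arrow(0.3, 0.1))
    assert d.r_x[0, 0] == pytest.approx(0.75)
    assert d.r_y[0, 0] == pytest.approx(0.25)


def test_axis_aligned_arrow():
    d = normalize_and_transition(_diagram_with_arrow(0.0, -0.4))
    assert d.r_x[0, 0] == 0.0
    assert d.r_y[0, 0] == -1.0


def test_all_zero_arrows_rejected():
    with pytest.raises(ValueError):
        normalize_and_transition(_diagram_with_arrow(0.0, 0.0))


def _random_trajectories(rng, n=30):
    trajs = []
    for i in range(n):
        k = rng.integers(2, 12)
        trajs.append(
            Trajectory(f"t{i}", rng.random(k) * 50, rng.random(k) * 0.02, "variance")
        )
    return trajs


def test_normalization_identity_on_random_diagrams():
    rng = np.random.default_rng(0)
    for _ in range(30):
        d = normalize_and_transition(bin_and_average(_random_trajectories(rng)))
        ok = np.isfinite(d.r_x)
        s = np.abs(d.r_x[ok]) + np.abs(d.r_y[ok])
        assert np.allclose(s, 1.0, rtol=0, atol=1e-12)


def test_segment_conservation():
    rng = np.random.default_rng(1)
    trajs = _random_trajectories(rng)
    d = bin_and_average(trajs)
    assert d.total_segments == sum(t.n_segments for t in trajs)


def test_reporter_rescaling_leaves_probabilities_unchanged():
    rng = np.random.default_rng(2)
    trajs = _random_trajectories(rng)
    scaled = [Trajectory(t.cell_id, t.x * 7.3, t.y, t.metric_kind) for t in trajs]
    d1 = normalize_and_transition(bin_and_average(trajs))
    d2 = normalize_and_transition(bin_and_average(scaled))
    ok = np.isfinite(d1.r_x)
    assert np.array_equal(ok, np.isfinite(d2.r_x))
    assert np.allclose(d1.r_x[ok], d2.r_x[ok])
    assert np.allclose(d1.r_y[ok], d2.r_y[ok])


def test_single_segment_fills_only_its_start_block():
    t = Trajectory("s", [0.1, 0.9], [0.1, 0.1], "variance")
    d = bin_and_average([t], n_blocks_x=3, n_blocks_y=3)
    assert d.counts.sum() == 1
    # start y equals the global y max, so the segment sits in the top y block
    assert d.counts[0, 2] == 1
    assert d.arrow_x[0, 2] == pytest.approx(0.8)
    assert d.arrow_y[0, 2] == pytest.approx(0.0)


def test_opposite_segments_cancel_to_zero_arrow():
    t1 = Trajectory("a", [0.10, 0.30], [0.10, 0.30], "variance")
    t2 = Trajectory("b", [0.12, -0.08], [0.11, -0.09], "variance")
    d = bin_and_average([t1, t2], n_blocks_x=2, n_blocks_y=2)
    assert d.counts[0, 0] == 2
    assert d.arrow_x[0, 0] == pytest.approx(0.0)
    assert d.arrow_y[0, 0] == pytest.approx(0.0)


def test_top_edge_points_belong_to_last_block():
    t = Trajectory("e", [1.0, 0.5], [1.0, 0.5], "variance")
    d = bin_and_average([t], n_blocks_x=4, n_blocks_y=4)
    assert d.counts[3, 3] == 1


def test_build_trajectories_requires_reporter_and_min_duration(make_trace):
    no_rep = make_trace(np.ones(30), cell_id="norep")
    with pytest.raises(MissingChannelError, match="reporter"):
        build_trajectories([no_rep])

    short = make_trace(np.ones(19), cell_id="short", reporter=np.zeros(19))  # 90 min
    assert build_trajectories([short]) == []
    long = make_trace(np.ones(30), cell_id="long", reporter=np.linspace(0, 1, 30))
    trajs = build_trajectories([long])
    assert [t.cell_id for t in trajs] == ["long"]


def test_constant_signals_give_zero_displacement(make_trace):
    tr = make_trace(np.ones(30), reporter=np.full(30, 5.0))
    (traj,) = build_trajectories([tr])
    assert np.all(np.diff(traj.x) == 0) and np.all(np.diff(traj.y) == 0)


def test_differentiation_cohort_flows_to_low_variance_high_reporter():
    """Cells whose pulses shut down while the reporter rises trace paths from
    (low reporter, pulsing variance) toward (high reporter, near-zero
    variance): late trajectory points must sit at higher reporter and lower
    variance than early ones."""
    cfgs = [
        SimConfig(seed=40 + i, reporter_onset_model="coupled_to_pulse_shutdown",
                  shutdown_time_h=6.0 + 3.0 * i, label=f"d{i}")
        for i in range(4)
    ]
    trajs = build_trajectories(simulate_cohort(cfgs, 5))
    assert len(trajs) == 20
    start_x = np.mean([t.x[0] for t in trajs])
    end_x = np.mean([t.x[-1] for t in trajs])
    end_y = np.mean([t.y[-1] for t in trajs])
    early_y = np.mean([t.y[: len(t.y) // 3].mean() for t in trajs])
    assert end_x > start_x
    assert end_y < early_y
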