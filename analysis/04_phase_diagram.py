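"""Phase diagram of ERK moving variance vs. reporter moving mean.

Builds per-cell trajectories from the differentiating cohort (50-min
windows, traces > 90 min), bins them into a 10x10 vector field, normalizes
the arrows, and summarizes the flow: in the pulsing region (low reporter,
elevated ERK variance) arrows should point toward increasing reporter and
decreasing variance — the differentiation transition.
"""

import json

import numpy as np

from erkpulse.phase import bin_and_average, build_trajectories, normalize_and_transition
from erkpulse.traces import compute_ratio, read_tracks
from _common import RESULTS, SCRATCH


def main() -> None:
    traces = compute_ratio(read_tracks(SCRATCH / "traces_differentiating.csv"))
    trajs = build_trajectories(traces, window_min=50.0, metric_kind="variance")
    diag = normalize_and_transition(bin_and_average(trajs, 10, 10))

    ok = np.isfinite(diag.r_x)
    sums = np.abs(diag.r_x[ok]) + np.abs(diag.r_y[ok])
    print(f"{len(trajs)} trajectories, {diag.total_segments} segments, "
          f"{int(ok.sum())} populated blocks")
    print(f"|r_x|+|r_y| over populated blocks: min {sums.min():.12f}, max {sums.max():.12f}")

    nx, ny = diag.n_blocks
    region = np.zeros((nx, ny), dtype=bool)
    region[: nx // 2, 2:] = True
    region &= diag.counts >= 10
    w = diag.counts[region]
    rx = float(np.average(diag.r_x[region], weights=w))
    ry = float(np.average(diag.r_y[region], weights=w))
    print(f"high-variance/low-reporter region ({int(region.sum())} blocks): "
          f"mean r_x {rx:+.3f} (reporter), mean r_y {ry:+.3f} (ERK variance)")

    payload = {
        "metric_kind": diag.metric_kind,
        "x_edges": diag.x_edges.tolist(),
        "y_edges": diag.y_edges.tolist(),
        "counts": diag.counts.tolist(),
        "r_x": np.where(np.isfinite(diag.r_x), diag.r_x, None).tolist(),
        "r_y": np.where(np.isfinite(diag.r_y), diag.r_y, None).tolist(),
        "flow_region": {"mean_r_x": rx, "mean_r_y": ry},
    }
    (RESULTS / "phase_diagram.json").write_text(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
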