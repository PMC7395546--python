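"""End-to-end orchestration: simulate -> ingest -> detect -> variance -> phase -> rdf.

A run is driven by a JSON :class:`RunConfig`; every stage's parameters and
the master seed are echoed into a manifest listing each produced file with
its SHA-256 checksum, so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .phase import bin_and_average, build_trajectories, normalize_and_transition
from .pulses import PulseParams, classify_pulse_class, detect_pulses, gate_basal
from .simulate import SimConfig, SpatialSimConfig, simulate_cohort, simulate_spatial_pattern
from .spatial import FieldOfInterest, rdf_analysis
from .traces import compute_ratio, filter_min_duration, read_tracks, traces_to_table, write_tracks
from .variance import moving_variance, pulse_level_score

__all__ = ["RunConfig", "run_pipeline", "summarize_cohort", "PipelineError"]

STAGE_ORDER = ["simulate", "ingest", "detect", "variance", "phase", "rdf"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class RunConfig:
    """Validated run configuration (a thin wrapper over a JSON-able dict)."""

    def __init__(self, data: dict):
        if "seed" not in data:
            raise ValueError("run config must set a master 'seed'")
        unknown = set(data) - set(STAGE_ORDER) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        self.data = data
        self.seed = int(data["seed"])

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(json.load(fh))

    def stages(self) -> list[str]:
        return [s for s in STAGE_ORDER if s in self.data]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarize_cohort(
    traces,
    pulse_sets,
    window_series=None,
    basal_gate: float = 1.2,
    lower_basal_gate: float | None = None,
    pulse_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-cell summary with the four-state (basal x pulse) labels.

    Basal tiers: "hi" at mean ratio >= ``basal_gate`` (1.2 FRET/CFP), "lo"
    below ``lower_basal_gate`` (default: the cohort's 25th percentile of the
    mean ratio, since only the upper gate is quantified), "mid" in between.
    Pulse class uses the 1.5 pulses/h threshold. The state label combines
    the two, e.g. ``Basal^hi-Pulse^lo``.
    """
    traces = list(traces)
    pmap = {p.cell_id: p for p in pulse_sets}
    wmap = {w.cell_id: w for w in window_series} if window_series else {}
    missing = [t.cell_id for t in traces if t.cell_id not in pmap]
    if missing:
        raise ValueError(f"missing pulse metrics for cell(s): {missing[:5]}")

    means = np.array([t.mean_ratio for t in traces]) if traces else np.empty(0)
    if lower_basal_gate is None:
        lower_basal_gate = float(np.percentile(means, 25)) if means.size else 0.0
        lower_basal_gate = min(lower_basal_gate, basal_gate)

    rows = []
    for tr in traces:
        ps = pmap[tr.cell_id]
        freq = ps.frequency_per_h
        pulse_cls = classify_pulse_class(freq, pulse_threshold)
        upper = gate_basal(tr.mean_ratio, basal_gate)
        tier = "hi" if upper == "high" else ("lo" if tr.mean_ratio < lower_basal_gate else "mid")
        ws = wmap.get(tr.cell_id)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "label": tr.label,
                "mean_ratio": tr.mean_ratio,
                "pulse_frequency_per_h": freq,
                "n_pulses": ps.n_pulses,
                "pulse_level": pulse_level_score(ws) if ws is not None and len(ws) else np.nan,
                "pulse_class": pulse_cls,
                "basal_gate": upper,
                "basal_tier": tier,
                "state": f"Basal^{tier}-Pulse^{'hi' if pulse_cls == 'high' else 'lo'}",
                "reporter_mean": float(np.nanmean(tr.reporter)) if tr.reporter is not None else np.nan,
            }
        )
    cols = [
        "cell_id", "label", "mean_ratio", "pulse_frequency_per_h", "n_pulses",
        "pulse_level", "pulse_class", "basal_gate", "basal_tier", "state", "reporter_mean",
    ]
    return pd.DataFrame(rows, columns=cols)


def _sim_configs_from(section: dict, master_seed: int) -> list[SimConfig]:
    cohorts = section.get("cohorts", [section])
    configs = []
    for i, c in enumerate(cohorts):
        c = dict(c)
        c.pop("n_traces", None)
        c.setdefault("seed", master_seed + i)
        configs.append(SimConfig(**c))
    return configs


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}
    traces = None

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        produced[name] = _sha256(path)
        return path

    for stage in config.stages():
        sect = config.data[stage]
        try:
            if stage == "simulate":
                n = int(sect.get("n_traces", 10))
                cfgs = _sim_configs_from(sect, config.seed)
                traces = simulate_cohort(cfgs, n)
                table = traces_to_table(traces)
                emit("traces.csv", lambda p: write_tracks(table, p))
            elif stage == "ingest":
                path = sect.get("path")
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"input file not found: {path}")
                if path is not None:
                    traces = compute_ratio(read_tracks(path))
                if traces is None:
                    raise PipelineError("ingest: no input path and no simulated traces")
                if "min_duration_min" in sect:
                    traces = filter_min_duration(traces, sect["min_duration_min"])
                emit("ingested.csv", lambda p: write_tracks(traces_to_table(traces), p))
            elif stage == "detect":
                if traces is None:
                    raise PipelineError("detect: no traces available")
                params = PulseParams(**sect.get("params", {}))
                pulse_sets = [detect_pulses(tr, params) for tr in traces]
                wss = [
                    moving_variance(tr, sect.get("window_min", 50.0))
                    for tr in traces
                    if tr.span_h >= sect.get("window_min", 50.0) / 60.0
                ]
                rows = [
                    {"cell_id": ps.cell_id, "peak_time_h": t, "amplitude": a, "duration_h": d}
                    for ps in pulse_sets
                    for t, a, d in zip(ps.peak_times_h, ps.amplitudes, ps.durations_h)
                ]
                emit("pulses.csv", lambda p: pd.DataFrame(
                    rows, columns=["cell_id", "peak_time_h", "amplitude", "duration_h"]
                ).to_csv(p, index=False))
                summary = summarize_cohort(traces, pulse_sets, wss)
                emit("cell_summary.csv", lambda p: summary.to_csv(p, index=False))
            elif stage == "variance":
                if traces is None:
                    raise PipelineError("variance: no traces available")
                wmin = sect.get("window_min", 50.0)
                rows = []
                for tr in traces:
                    if tr.span_h < wmin / 60.0:
                        continue
                    ws = moving_variance(tr, wmin)
                    for i in range(len(ws)):
                        rows.append(
                            {
                                "cell_id": ws.cell_id,
                                "window_center_h": ws.window_centers_h[i],
                                "erk_moving_variance": ws.erk_moving_variance[i],
                                "erk_moving_mean": ws.erk_moving_mean[i],
                            }
                        )
                emit("windows.csv", lambda p: pd.DataFrame(rows).to_csv(p, index=False))
            elif stage == "phase":
                if traces is None:
                    raise PipelineError("phase: no traces available")
                trajs = build_trajectories(
                    traces,
                    window_min=sect.get("window_min", 50.0),
                    metric_kind=sect.get("metric", "variance"),
                    min_duration_min=sect.get("min_duration_min", 90.0),
                )
                diag = normalize_and_transition(
                    bin_and_average(trajs, sect.get("n_blocks_x", 10), sect.get("n_blocks_y", 10))
                )
                payload = {
                    "metric_kind": diag.metric_kind,
                    "x_edges": diag.x_edges.tolist(),
                    "y_edges": diag.y_edges.tolist(),
                    "counts": diag.counts.tolist(),
                    "r_x": np.where(np.isfinite(diag.r_x), diag.r_x, None).tolist(),
                    "r_y": np.where(np.isfinite(diag.r_y), diag.r_y, None).tolist(),
                }
                emit("phase.json", lambda p: p.write_text(json.dumps(payload, indent=1)))
            elif stage == "rdf":
                spat = SpatialSimConfig(
                    seed=sect.get("seed", config.seed),
                    n_points=sect.get("n_points", 1000),
                    field=FieldOfInterest.rectangle(*sect.get("field_um", (1000.0, 1000.0))),
                    process=sect.get("process", "csr"),
                    cluster_sd_um=sect.get("cluster_sd_um", 25.0),
                    mark_model=sect.get("mark_model", "independent"),
                )
                pattern = simulate_spatial_pattern(spat)
                emit("points.csv", lambda p: pattern.points.to_csv(p, index=False))
                res = rdf_analysis(
                    pattern.points,
                    pattern.field,
                    n_null_realizations=sect.get("n_null", 50),
                    seed=config.seed,
                )
                df = pd.DataFrame(
                    {
                        "r_um": res.r_centers_um,
                        "g": res.g,
                        "null_mean": res.null_mean,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "classification": res.classification,
                    }
                )
                emit("rdf.csv", lambda p: df.to_csv(p, index=False))
        except Exception as exc:  # annotate with the failing stage
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "erkpulse_version": __version__,
        "seed": config.seed,
        "config": config.data,
        "config_hash": config.hash(),
        "files": produced,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
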