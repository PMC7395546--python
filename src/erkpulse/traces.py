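"""Tracked single-cell time series: containers, CSV I/O, ratio computation.

The canonical on-disk format is a flat CSV track table, one row per
(cell, frame), as exported by automated trackers::

    cell_id,frame,time_h,x_um,y_um,cfp,fret[,reporter]

ERK activity is the dimensionless FRET/CFP ratio of the EKAR-EV biosensor;
the optional ``reporter`` column carries a differentiation-reporter
intensity (e.g. an Involucrin reporter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "read_tracks",
    "write_tracks",
    "compute_ratio",
    "traces_to_table",
    "filter_min_duration",
]

REQUIRED_COLUMNS = ["cell_id", "frame", "time_h", "x_um", "y_um", "cfp", "fret"]
OPTIONAL_COLUMNS = ["reporter"]


class SchemaError(ValueError):
    """A track table is missing required columns."""


class ValidationError(ValueError):
    """A track table violates a structural invariant."""


@dataclass
class Trace:
    """One cell's time series of ERK activity (FRET/CFP ratio).

    Times are in hours and strictly increasing; positions in micrometres.
    ``reporter`` is an arbitrary-unit differentiation-reporter intensity.
    """

    cell_id: str
    times_h: np.ndarray
    ratio: np.ndarray
    x_um: np.ndarray | None = None
    y_um: np.ndarray | None = None
    reporter: np.ndarray | None = None
    cfp: np.ndarray | None = None
    fret: np.ndarray | None = None
    label: str = ""
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.size < 2:
            raise ValidationError(
                f"trace {self.cell_id!r}: need at least 2 samples, got {self.times_h.size}"
            )
        if self.ratio.shape != self.times_h.shape:
            raise ValidationError(f"trace {self.cell_id!r}: times/ratio length mismatch")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValidationError(f"trace {self.cell_id!r}: times not strictly increasing")
        for name in ("x_um", "y_um", "reporter", "cfp", "fret"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times_h.shape:
                    raise ValidationError(
                        f"trace {self.cell_id!r}: {name} length mismatch"
                    )
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.times_h.size

    @property
    def span_h(self) -> float:
        """Observed span (last minus first sample time), hours."""
        return float(self.times_h[-1] - self.times_h[0])

    @property
    def mean_ratio(self) -> float:
        return float(np.nanmean(self.ratio))


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a CSV track table.

    Returns the table sorted by (cell_id, frame). Rows with missing numeric
    values are dropped with a warning naming their line numbers. Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for duplicated (cell_id, frame) keys or non-monotone time within a cell.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    numeric_cols = [c for c in table.columns if c != "cell_id"]
    for col in numeric_cols:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    check_cols = [c for c in REQUIRED_COLUMNS if c != "cell_id"]
    bad = table[check_cols].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (table.index[bad] + 2).tolist()
        warnings.warn(
            f"dropped {bad.sum()} malformed row(s) at line(s) {lines}", stacklevel=2
        )
        table = table[~bad]

    dup = table.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        keys = table.loc[dup, ["cell_id", "frame"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicated (cell_id, frame) key(s): {keys[:5]}")

    table = table.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    for cid, grp in table.groupby("cell_id", sort=False):
        if np.any(np.diff(grp["time_h"].to_numpy()) <= 0):
            raise ValidationError(f"non-monotone time within cell {cid!r}")
    return table


def write_tracks(table: pd.DataFrame, path) -> None:
    """Write a track table as CSV (round-trips finite floats bit-exactly)."""
    table.to_csv(path, index=False, float_format="%.17g")


def compute_ratio(table: pd.DataFrame) -> list[Trace]:
    """Build per-cell :class:`Trace` objects with ratio = fret / cfp.

    Timepoints with cfp <= 0 (or non-finite channels) are dropped and
    counted in ``Trace.n_dropped``. Cells left with fewer than 2 valid
    timepoints are omitted with a warning.
    """
    has_reporter = "reporter" in table.columns
    traces: list[Trace] = []
    for cid, grp in table.groupby("cell_id", sort=True):
        cfp = grp["cfp"].to_numpy(dtype=float)
        fret = grp["fret"].to_numpy(dtype=float)
        valid = np.isfinite(cfp) & np.isfinite(fret) & (cfp > 0) & (fret >= 0)
        n_dropped = int((~valid).sum())
        if valid.sum() < 2:
            warnings.warn(
                f"cell {cid!r}: fewer than 2 valid timepoints, omitted", stacklevel=2
            )
            continue
        g = grp[valid]
        traces.append(
            Trace(
                cell_id=str(cid),
                times_h=g["time_h"].to_numpy(dtype=float),
                ratio=fret[valid] / cfp[valid],
                x_um=g["x_um"].to_numpy(dtype=float),
                y_um=g["y_um"].to_numpy(dtype=float),
                reporter=g["reporter"].to_numpy(dtype=float) if has_reporter else None,
                cfp=cfp[valid],
                fret=fret[valid],
                n_dropped=n_dropped,
            )
        )
    return traces


def traces_to_table(traces: list[Trace], cfp_level: float = 1000.0) -> pd.DataFrame:
    """Serialize traces into the track-table dialect.

    Traces that lack raw channels (e.g. simulated ones) are written with a
    constant CFP of ``cfp_level`` and FRET = ratio * cfp, so the ratio is
    recovered on re-ingestion.
    """
    rows = []
    for tr in traces:
        n = len(tr)
        cfp = tr.cfp if tr.cfp is not None else np.full(n, float(cfp_level))
        fret = tr.fret if tr.fret is not None else tr.ratio * cfp
        frame = np.arange(n)
        df = pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "frame": frame,
                "time_h": tr.times_h,
                "x_um": tr.x_um if tr.x_um is not None else np.zeros(n),
                "y_um": tr.y_um if tr.y_um is not None else np.zeros(n),
                "cfp": cfp,
                "fret": fret,
            }
        )
        if tr.reporter is not None:
            df["reporter"] = tr.reporter
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def filter_min_duration(traces, min_duration_min: float = 90.0) -> list[Trace]:
    """Keep traces whose observed span strictly exceeds ``min_duration_min``.

    The strict inequality means a trace spanning exactly 90 min is dropped.
    """
    thr_h = float(min_duration_min) / 60.0
    return [tr for tr in traces if tr.span_h > thr_h]
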