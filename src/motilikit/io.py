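"""Readers and writers for track tables and result tables.

Two input dialects are supported:

* ``generic`` — header ``track_id,frame,x,y`` (comma- or tab-separated).
* ``trackmate`` — a TrackMate spots export with columns ``TRACK_ID``,
  ``FRAME``, ``POSITION_X``, ``POSITION_Y``; the extra descriptive header
  rows that TrackMate emits below the column names are skipped.

Coordinates are converted to micrometres via a per-file calibration factor
(µm per coordinate unit, default 1.0). Frame indices must be consecutive
within a track: missing frames are rejected rather than interpolated, so
the sampled dynamics are never silently altered.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .trajectory import CellType, Scenario, Trajectory

_GENERIC_COLS = ["track_id", "frame", "x", "y"]
_TRACKMATE_COLS = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _load_generic(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in _GENERIC_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df[list(df.columns)]


def _load_trackmate(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in _TRACKMATE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.rename(columns=_TRACKMATE_COLS)
    # TrackMate >= 7 inserts human-readable name/unit rows under the header.
    for col in ("frame", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["frame", "x", "y"])
    return df


def read_tracks(
    path: str | Path,
    dialect: str = "generic",
    calibration: float = 1.0,
    dt: float = 0.5,
    cell_type: CellType | str | None = None,
    scenario: Scenario | str | None = None,
) -> list[Trajectory]:
    """Read a track table into a list of :class:`Trajectory`.

    Parameters
    ----------
    path
        Delimited text file in one of the supported dialects.
    dialect
        ``"generic"`` or ``"trackmate"``.
    calibration
        Micrometres per coordinate unit (default 1.0).
    dt
        Sampling interval in seconds.
    cell_type, scenario
        Optional cohort labels applied to every track in the file.

    Raises
    ------
    FormatError
        Missing columns or unknown dialect.
    ValidationError
        Non-consecutive frame indices within a track (gap locations are
        listed in the message), or an empty file.
    """
    path = Path(path)
    if dialect == "generic":
        df = _load_generic(path)
    elif dialect == "trackmate":
        df = _load_trackmate(path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    if df.empty:
        raise ValidationError(f"{path}: no track rows found")

    if cell_type is not None:
        cell_type = CellType(cell_type)
    if scenario is not None:
        scenario = Scenario(scenario)

    trajectories: list[Trajectory] = []
    for track_id, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy(dtype=float)
        gaps = np.flatnonzero(np.diff(frames) != 1)
        if gaps.size:
            locs = ", ".join(
                f"{int(frames[g])}->{int(frames[g + 1])}" for g in gaps[:10]
            )
            raise ValidationError(
                f"{path}: track {track_id!r} has non-uniform frame spacing "
                f"at {locs}"
            )
        pos = group[["x", "y"]].to_numpy(dtype=float) * float(calibration)
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                positions=pos,
                dt=dt,
                t0=float(frames[0]) * dt,
                cell_type=cell_type,
                scenario=scenario,
            )
        )
    return trajectories


def write_tracks(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories in the generic ``track_id,frame,x,y`` format."""
    rows = []
    for traj in trajectories:
        n = len(traj)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": np.repeat(traj.track_id, n),
                    "frame": np.arange(n),
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                }
            )
        )
    if not rows:
        raise ValidationError("no trajectories to write")
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


_RESULT_COLS = [
    "metric",
    "nonenucleated_median",
    "nonenucleated_iqr",
    "enucleated_median",
    "enucleated_iqr",
    "p_value",
    "z_stat",
]


def write_results_table(summaries: Sequence, path: str | Path) -> None:
    """Write cohort summaries as a delimited table, one metric per row.

    Mirrors the two-cohort comparison layout: metric name, median/IQR per
    cohort, Wilcoxon P-value and Z. Rereading with
    :func:`read_results_table` yields identical values.
    """
    rows = []
    for s in summaries:
        d = dataclasses.asdict(s) if dataclasses.is_dataclass(s) else dict(s)
        groups = list(d["medians"])
        g1 = groups[0]
        g2 = groups[1] if len(groups) > 1 else groups[0]
        rows.append(
            {
                "metric": d["metric_name"],
                "nonenucleated_median": d["medians"][g1],
                "nonenucleated_iqr": d["iqrs"][g1],
                "enucleated_median": d["medians"][g2],
                "enucleated_iqr": d["iqrs"][g2],
                "p_value": d["p_value"],
                "z_stat": d["z_stat"],
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLS).to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path)
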