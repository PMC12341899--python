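"""Directional and kinematic descriptors of a trajectory.

All quantities are computed from the raw sampled path: the displacement
cosine and 45°-sector of the net displacement relative to the stimulus
axis, the intensity of response (net displacement magnitude, reported in
millimetres), the directionality ratio (net / total path length, 1 for a
straight path), and the average speed (total path length / duration,
µm/s). Trajectories with zero net displacement have no defined direction
and yield NaN cosine/angle; cohort statistics exclude them with a logged
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .trajectory import StimulusFrame, Trajectory, to_step_series

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class KinematicSummary:
    """Per-trajectory kinematic descriptors."""

    track_id: str
    cosine: float
    angle_deg: float
    sector: int  # -1 when direction undefined
    ir_mm: float
    dr: float
    as_um_s: float


def _net_displacement(traj: Trajectory) -> np.ndarray:
    return traj.positions[-1] - traj.positions[0]


def displacement_cosine(traj: Trajectory, frame: StimulusFrame) -> float:
    """Cosine of the angle between net displacement and the stimulus axis.

    +1 means motion straight along the axis (toward the cathode under the
    default frame), -1 straight against it. NaN if the trajectory closes
    on itself (zero net displacement).
    """
    d = _net_displacement(traj)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0:
        return float("nan")
    return float(np.dot(d, frame.axis) / norm)


def displacement_angle(traj: Trajectory, frame: StimulusFrame) -> float:
    """Angle (degrees, [0, 360)) of net displacement, measured from the
    stimulus axis counterclockwise. NaN for zero net displacement."""
    d = _net_displacement(traj)
    if float(np.hypot(d[0], d[1])) == 0.0:
        return float("nan")
    # rotate so the stimulus axis is 0 degrees
    ax, ay = frame.axis
    x = d[0] * ax + d[1] * ay
    y = -d[0] * ay + d[1] * ax
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def sector_of(angle_deg: float) -> int:
    """Half-open 45° sector index: sector k covers [k*45, (k+1)*45)."""
    if not np.isfinite(angle_deg):
        return -1
    return int((angle_deg % 360.0) // 45.0)


def sector_histogram(trajectories, frame: StimulusFrame) -> np.ndarray:
    """Percentage of trajectories finishing within each 45° sector.

    Zero-net-displacement trajectories are excluded; percentages sum to
    100 over the included ones.
    """
    sectors = [
        sector_of(displacement_angle(t, frame)) for t in trajectories
    ]
    sectors = [s for s in sectors if s >= 0]
    if not sectors:
        raise DegenerateInputError(
            "all trajectories have zero net displacement; no histogram"
        )
    counts = np.bincount(sectors, minlength=8).astype(float)
    return 100.0 * counts / counts.sum()


def intensity_of_response(traj: Trajectory) -> float:
    """Modulus of the start-to-end displacement vector, in millimetres."""
    d = _net_displacement(traj)
    return float(np.hypot(d[0], d[1])) / UM_PER_MM


def path_length(traj: Trajectory) -> float:
    """Total path length in micrometres."""
    return float(to_step_series(traj).values.sum())


def directionality_ratio(traj: Trajectory) -> float:
    """Net displacement / total path length, in [0, 1].

    1 for a perfectly straight path, 0 for a closed loop; NaN for a
    stationary trajectory (zero path length).
    """
    total = path_length(traj)
    if total == 0.0:
        return float("nan")
    d = _net_displacement(traj)
    return float(np.hypot(d[0], d[1])) / total


def average_speed(traj: Trajectory) -> float:
    """Total path length / total duration, in µm/s."""
    return path_length(traj) / traj.duration


def kinematic_summary(traj: Trajectory, frame: StimulusFrame) -> KinematicSummary:
    angle = displacement_angle(traj, frame)
    return KinematicSummary(
        track_id=traj.track_id,
        cosine=displacement_cosine(traj, frame),
        angle_deg=angle,
        sector=sector_of(angle),
        ir_mm=intensity_of_response(traj),
        dr=directionality_ratio(traj),
        as_um_s=average_speed(traj),
    )
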