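"""Core domain types for tracked cell-migration data.

A :class:`Trajectory` is the atomic analysis unit: a uniformly sampled 2D
path in micrometres. Its per-frame displacement magnitudes form a
:class:`StepSeries` (the "move-step" series), which is the input for the
fluctuation and entropy analyses. A :class:`StimulusFrame` fixes the
reference axis against which directional statistics (displacement cosines,
sector histograms) are computed; by convention +x points toward the cathode
and the chemoattractant source lies toward -x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DegenerateInputError, ValidationError

#: Recording protocol of the reference experiments: two images per second
#: for 34 min 10 s, i.e. 4,100 frames spanning 2,049.5 s.
FRAME_RATE_HZ = 2.0
FRAME_INTERVAL_S = 0.5
RECORDING_DURATION_S = 2050.0  # 34 min 10 s
RECORDING_FRAMES = 4100


def frames_at_rate(duration_s: float, rate_hz: float = FRAME_RATE_HZ) -> int:
    """Number of frames acquired at ``rate_hz`` over ``duration_s`` seconds."""
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    return int(round(duration_s * rate_hz))


class CellType(str, Enum):
    NUCLEATED = "nucleated"
    CYTOPLAST = "cytoplast"


class Scenario(str, Enum):
    """Experimental scenario: no stimulus, electric field, peptide
    gradient, or both stimuli simultaneously."""

    SC1 = "Sc1"
    SC2 = "Sc2"
    SC3 = "Sc3"
    SC4 = "Sc4"


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled 2D cell track.

    Parameters
    ----------
    track_id
        Text label identifying the cell.
    positions
        ``(n, 2)`` array of (x, y) coordinates in micrometres, ordered by
        frame. ``n >= 2`` and all coordinates finite.
    dt
        Sampling interval in seconds (default 0.5 s, i.e. 2 Hz).
    t0
        Time of the first frame in seconds.
    cell_type, scenario
        Optional cohort labels.
    """

    track_id: str
    positions: np.ndarray
    dt: float = FRAME_INTERVAL_S
    t0: float = 0.0
    cell_type: CellType | None = None
    scenario: Scenario | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValidationError(
                f"positions must be (n, 2), got shape {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise DegenerateInputError(
                f"trajectory {self.track_id!r} has {pos.shape[0]} frames; "
                "need at least 2"
            )
        if not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"trajectory {self.track_id!r} contains non-finite coordinates"
            )
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Total duration ``(n - 1) * dt`` in seconds."""
        return (self.n_frames - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def with_positions(self, positions: np.ndarray, suffix: str = "") -> "Trajectory":
        """Copy of this trajectory with new coordinates (labels preserved)."""
        return Trajectory(
            track_id=self.track_id + suffix,
            positions=positions,
            dt=self.dt,
            t0=self.t0,
            cell_type=self.cell_type,
            scenario=self.scenario,
        )


@dataclass(frozen=True)
class StepSeries:
    """Per-frame move-step lengths (micrometres per frame) of a track."""

    values: np.ndarray
    dt: float = FRAME_INTERVAL_S
    source_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValidationError("step values must be a non-empty 1D array")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("step values contain non-finite entries")
        if np.any(vals < 0):
            raise ValidationError("step lengths must be nonnegative")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StimulusFrame:
    """Reference direction of the applied stimulus in the chamber plane.

    ``axis`` is a unit vector; the default ``(1, 0)`` points toward the
    cathode on the right of the chamber (``positive_sense`` documents the
    physical meaning of the + direction).
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    positive_sense: str = "cathode_right"

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (2,):
            raise ValidationError("stimulus axis must be a 2-vector")
        norm = float(np.hypot(ax[0], ax[1]))
        if not np.isclose(norm, 1.0, atol=1e-9):
            if norm == 0:
                raise ValidationError("stimulus axis must be nonzero")
            ax = ax / norm
        object.__setattr__(self, "axis", ax)


def to_step_series(traj: Trajectory) -> StepSeries:
    """Euclidean per-frame displacement magnitudes of a trajectory.

    The resulting series has length ``len(traj) - 1`` and is invariant
    under global translation and rotation of the path.
    """
    if len(traj) < 2:
        raise DegenerateInputError("need at least 2 positions for steps")
    diffs = np.diff(traj.positions, axis=0)
    values = np.hypot(diffs[:, 0], diffs[:, 1])
    return StepSeries(values=values, dt=traj.dt, source_id=traj.track_id)
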