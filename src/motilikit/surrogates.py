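"""Shuffled-surrogate nulls.

A surrogate destroys all temporal structure of a track while preserving
its value distribution exactly: position samples (for trajectory-level
metrics: MSD, DFA, kinematics) or move-step values (for rmsf/ApEn) are
put in uniformly random order. The nominal elementary-transposition count
is retained as a config echo; a uniform permutation is the distributional
fixed point of any sufficiently long transposition shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .trajectory import StepSeries, Trajectory


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate-generation settings.

    ``n_shuffle_ops`` documents the number of elementary randomization
    operations the permutation stands for (default 2e5 per trajectory).
    """

    n_surrogates: int = 1
    n_shuffle_ops: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 1 or self.n_shuffle_ops < 1:
            raise ConfigError("surrogate counts must be >= 1")


def shuffle_trajectory(traj: Trajectory, spec: SurrogateSpec) -> list[Trajectory]:
    """Surrogate trajectories with time-randomized position samples.

    The multiset of positions is preserved exactly; track ids get a
    ``_shuffled`` suffix. Reproducible given ``spec.seed``.
    """
    if len(traj) < 3:
        raise DegenerateInputError("need >= 3 positions to permute")
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_surrogates):
        perm = rng.permutation(len(traj))
        suffix = "_shuffled" if spec.n_surrogates == 1 else f"_shuffled{i}"
        out.append(traj.with_positions(traj.positions[perm], suffix=suffix))
    return out


def shuffle_series(series: StepSeries, spec: SurrogateSpec) -> list[StepSeries]:
    """Surrogate step series with values in uniformly random order.

    Mean and SD are exactly those of the original (permutation
    invariants).
    """
    if len(series) < 3:
        raise DegenerateInputError("need >= 3 values to permute")
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_surrogates):
        perm = rng.permutation(len(series))
        suffix = "_shuffled" if spec.n_surrogates == 1 else f"_shuffled{i}"
        out.append(
            StepSeries(
                values=series.values[perm],
                dt=series.dt,
                source_id=series.source_id + suffix,
            )
        )
    return out
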