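"""End-to-end orchestration: ingest or simulate, compute all metrics,
build shuffled surrogates, and summarize cohorts.

Per trajectory the pipeline computes the eight standard metrics — rmsf
alpha, correlation time, MSD beta, DFA gamma (mean of the x- and
y-coordinate exponents), full-length ApEn of the move-step series, and
the three kinematic descriptors — plus the displacement cosine/angle/
sector against the stimulus axis. Surrogates shuffle the position order
for trajectory-level metrics and the move-step order for rmsf/ApEn.

One master seed fans out to per-trajectory child seeds, so runs are
bit-reproducible and stable under reordering. Per-trajectory failures
are recorded in the run log and reported as NaN; the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from .entropy import ApEnParams, apen, apen_profile
from .errors import MotilikitError
from .scaling import (
    correlation_time,
    dfa_curve,
    fit_scaling_exponent,
    log_spaced_scales,
    msd_curve,
    rmsf_curve,
)
from .stats import METRIC_COLUMNS, summarize_cohorts
from .surrogates import SurrogateSpec, shuffle_series, shuffle_trajectory
from .trajectory import StimulusFrame, Trajectory, to_step_series


@dataclass
class RunConfig:
    """Settings for one analysis run."""

    seed: int = 0
    dt: float = 0.5
    calibration: float = 1.0
    dialect: str = "generic"
    apen_m: int = 2
    apen_r: float = 0.2
    dfa_order: int = 1
    corr_margin: float = 0.05
    n_surrogates: int = 1
    compute_profiles: bool = True
    apen_profile_step: int = 50
    stimulus_axis: tuple[float, float] = (1.0, 0.0)


@dataclass
class RunResult:
    """Bundle of per-trajectory metrics, surrogate metrics, ApEn
    profiles, cohort summaries, and the run log."""

    metrics: pd.DataFrame
    surrogate_metrics: pd.DataFrame
    profiles: pd.DataFrame | None
    summaries: list
    log: list[str] = field(default_factory=list)


def _scales_for(n_steps: int) -> np.ndarray:
    """rmsf/DFA scale grid: log-spaced fit points in [8, n/8] plus the
    25-s correlation-time grid, all within the [4, n/4] precondition."""
    fit = log_spaced_scales(8, max(n_steps // 8, 9))
    grid = np.arange(50, n_steps // 4 + 1, 50)
    return np.unique(np.concatenate([fit, grid])) if grid.size else fit


def analyze_trajectory(
    traj: Trajectory,
    cfg: RunConfig,
    frame: StimulusFrame,
    log: list[str] | None = None,
) -> dict:
    """All per-trajectory metrics as a flat dict (NaN on failure)."""
    if log is None:
        log = []
    row: dict = {
        "track_id": traj.track_id,
        "cell_type": traj.cell_type.value if traj.cell_type else "",
        "scenario": traj.scenario.value if traj.scenario else "",
    }
    for col in METRIC_COLUMNS + ["cosine", "angle_deg", "sector"]:
        row[col] = np.nan

    params = ApEnParams(m=cfg.apen_m, r=cfg.apen_r)
    steps = to_step_series(traj)
    n_steps = len(steps)
    fit_range = (8.0, max(n_steps // 8, 9))

    try:
        curve = rmsf_curve(steps, scales=_scales_for(n_steps))
        fit = fit_scaling_exponent(curve, fit_range=fit_range)
        row["rmsf_alpha"] = fit.exponent
        ct = correlation_time(curve, fit, dt=traj.dt, margin=cfg.corr_margin)
        row["corr_time_min"] = ct.minutes
    except MotilikitError as exc:
        log.append(f"{traj.track_id}: rmsf failed: {exc}")

    try:
        mcurve = msd_curve(traj)
        row["msd_beta"] = fit_scaling_exponent(mcurve).exponent
    except MotilikitError as exc:
        log.append(f"{traj.track_id}: msd failed: {exc}")

    try:
        gammas = []
        for axis in (0, 1):
            dcurve = dfa_curve(
                traj.positions[:, axis],
                box_sizes=log_spaced_scales(8, max(len(traj) // 8, 9)),
                detrend_order=cfg.dfa_order,
            )
            gammas.append(fit_scaling_exponent(dcurve).exponent)
        row["dfa_gamma"] = float(np.mean(gammas))
    except MotilikitError as exc:
        log.append(f"{traj.track_id}: dfa failed: {exc}")

    try:
        row["apen"] = apen(steps, params=params, strict=False)
    except MotilikitError as exc:
        log.append(f"{traj.track_id}: apen failed: {exc}")

    summary = kin.kinematic_summary(traj, frame)
    row.update(
        ir_mm=summary.ir_mm,
        dr=summary.dr,
        as_um_s=summary.as_um_s,
        cosine=summary.cosine,
        angle_deg=summary.angle_deg,
        sector=summary.sector,
    )
    if not np.isfinite(summary.cosine):
        log.append(f"{traj.track_id}: zero net displacement; cosine undefined")
    return row


def _surrogate_row(
    traj: Trajectory, cfg: RunConfig, frame: StimulusFrame, seed: int,
    log: list[str],
) -> dict:
    """Metrics of one shuffled surrogate: position order randomized for
    MSD/DFA/kinematics, step order for rmsf/ApEn."""
    spec = SurrogateSpec(n_surrogates=1, seed=seed)
    sh_traj = shuffle_trajectory(traj, spec)[0]
    sh_steps = shuffle_series(to_step_series(traj), spec)[0]
    row = analyze_trajectory(sh_traj, cfg, frame, log=log)
    params = ApEnParams(m=cfg.apen_m, r=cfg.apen_r)
    n_steps = len(sh_steps)
    try:
        curve = rmsf_curve(sh_steps, scales=_scales_for(n_steps))
        fit = fit_scaling_exponent(curve, fit_range=(8.0, max(n_steps // 8, 9)))
        row["rmsf_alpha"] = fit.exponent
        ct = correlation_time(curve, fit, dt=traj.dt, margin=cfg.corr_margin)
        row["corr_time_min"] = ct.minutes
        row["apen"] = apen(sh_steps, params=params, strict=False)
    except MotilikitError as exc:
        log.append(f"{sh_steps.source_id}: surrogate series metrics failed: {exc}")
    return row


def run_analysis(
    trajectories: list[Trajectory],
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full metric/surrogate/summary pipeline on a cohort.

    If ``out_dir`` is given, writes ``metrics.csv``,
    ``surrogate_metrics.csv``, ``apen_profiles.csv``, ``summaries.csv``
    and ``run_log.txt`` there.
    """
    if cfg is None:
        cfg = RunConfig()
    frame = StimulusFrame(axis=np.asarray(cfg.stimulus_axis, dtype=float))
    log: list[str] = [f"config: {cfg}", f"n_trajectories: {len(trajectories)}"]
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(trajectories))

    rows, surrogate_rows, profile_rows = [], [], []
    params = ApEnParams(m=cfg.apen_m, r=cfg.apen_r)
    for traj, child in zip(trajectories, children):
        rows.append(analyze_trajectory(traj, cfg, frame, log=log))
        child_seeds = child.generate_state(cfg.n_surrogates) % (2**31)
        for s in child_seeds:
            surrogate_rows.append(_surrogate_row(traj, cfg, frame, int(s), log))
        if cfg.compute_profiles:
            try:
                prof = apen_profile(
                    to_step_series(traj), params=params, step=cfg.apen_profile_step
                )
                profile_rows.append(
                    {"track_id": traj.track_id}
                    | {int(w): v for w, v in zip(prof.window_lengths, prof.values)}
                )
            except MotilikitError as exc:
                log.append(f"{traj.track_id}: apen profile failed: {exc}")

    metrics = pd.DataFrame(rows)
    surrogate_metrics = pd.DataFrame(surrogate_rows)
    profiles = pd.DataFrame(profile_rows) if profile_rows else None

    summaries = []
    types = [t for t in pd.unique(metrics.get("cell_type", pd.Series([]))) if t]
    if len(types) == 2 and all(
        (metrics["cell_type"] == t).sum() >= 2 for t in types
    ):
        try:
            summaries = summarize_cohorts(metrics, group_col="cell_type")
        except MotilikitError as exc:
            log.append(f"cohort summary failed: {exc}")

    result = RunResult(
        metrics=metrics,
        surrogate_metrics=surrogate_metrics,
        profiles=profiles,
        summaries=summaries,
        log=log,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    from .io import write_results_table

    out_dir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out_dir / "metrics.csv", index=False)
    result.surrogate_metrics.to_csv(out_dir / "surrogate_metrics.csv", index=False)
    if result.profiles is not None:
        result.profiles.to_csv(out_dir / "apen_profiles.csv", index=False)
    if result.summaries:
        write_results_table(result.summaries, out_dir / "summaries.csv")
    (out_dir / "run_log.txt").write_text("\n".join(result.log) + "\n")
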