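"""Fluctuation-scaling analyses: rmsf, MSD, DFA, and exponent fitting.

Three curves, one fitting rule:

* **rmsf** — root mean square fluctuation of the cumulative profile of a
  move-step series: ``F(l) = std(y(k+l) - y(k))`` over all overlapping
  windows, where ``y`` is the cumulative sum of the mean-subtracted
  series. ``F(l) ~ l^alpha``; alpha = 0.5 for uncorrelated steps,
  alpha > 0.5 for positive long-range correlation.
* **MSD** — time-averaged mean squared displacement of the 2D path,
  ``MSD(tau) ~ tau^beta``; beta = 1 normal diffusion, beta = 2 ballistic.
* **DFA** — detrended fluctuation analysis (order-1 by default) of a 1D
  series: integrate the mean-subtracted series, remove a per-box
  least-squares polynomial trend in non-overlapping boxes (forward and
  reversed partitions averaged), ``F(n) ~ n^gamma``. For noise-like
  input gamma = 0.5 means no correlation; for Brownian-class input the
  neutral value is 1.5 and 1.5 < gamma < 2 is trend-reinforcing
  persistence.

Exponents are ordinary least-squares slopes in log10-log10 coordinates;
the base does not affect the exponent. The correlation time is the
largest scale up to which all local half-decade log-log slopes of the
rmsf curve stay above 0.5 + margin, reported in minutes on a 50-frame
(25 s at 2 Hz) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateCurveError
from .trajectory import StepSeries, Trajectory


@dataclass(frozen=True)
class ScalingCurve:
    """A fluctuation curve: F at each scale (lag or box size, frames)."""

    scales: np.ndarray
    values: np.ndarray
    kind: str  # rmsf | msd | dfa

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if scales.size < 2 or np.any(np.diff(scales) <= 0):
            raise ConfigError("scales must be strictly increasing, >= 2 entries")
        if scales.size != values.size:
            raise ConfigError("scales and values must have equal length")
        if np.any(values < 0):
            raise ConfigError("curve values must be nonnegative")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ScalingFit:
    """A fitted power-law exponent with its fit range and diagnostics."""

    exponent: float
    intercept: float
    fit_range: tuple[float, float]
    r_squared: float
    kind: str


@dataclass(frozen=True)
class CorrelationTime:
    """Duration of the correlated rmsf regime, snapped to a 25-s grid."""

    minutes: float
    crossover_scale: int  # frames
    no_correlated_regime: bool = False


def log_spaced_scales(lo: int, hi: int, num: int = 24) -> np.ndarray:
    """Unique integer scales approximately log-spaced in [lo, hi]."""
    if hi <= lo:
        raise ConfigError(f"need hi > lo, got [{lo}, {hi}]")
    return np.unique(np.round(np.geomspace(lo, hi, num)).astype(int))


def _series_values(series) -> np.ndarray:
    if isinstance(series, StepSeries):
        return series.values
    return np.asarray(series, dtype=float)


def _bridge_factor(hurst: float, scale: int, n: int) -> float:
    """Expected deflation of the lag-``scale`` squared fluctuation of a
    mean-subtracted profile, relative to ``scale^2H``.

    Subtracting the sample mean of the series pins the profile's endpoint
    at zero, turning it into an exact fractional-Brownian bridge; the
    second moment of the bridge increments, averaged over all window
    origins, is analytic in H and ``scale / n``.
    """
    k = np.arange(0, n - scale, dtype=float)
    h2 = 2.0 * hurst
    ed2 = (
        scale**h2
        - (scale / n)
        * ((k + scale) ** h2 - k**h2 + (n - k) ** h2 - (n - k - scale) ** h2)
        + (scale / n) ** 2 * n**h2
    )
    return float(ed2.mean() / scale**h2)


def rmsf_curve(series, scales=None, finite_size_correction: bool = True) -> ScalingCurve:
    """Root mean square fluctuation curve of a (step) series.

    ``F(l)`` is the root-mean-square of the increments ``y(k+l) - y(k)``
    of the cumulative mean-subtracted profile ``y`` over all overlapping
    windows of length ``l``. Scales must lie in ``[4, n/4]``.

    Subtracting the sample mean makes the profile a bridge, which
    deflates the large-scale fluctuations of persistent series (the
    fitted exponent of an fGn series would underestimate H by ~0.1 at
    H = 0.9 for n ~ 4000). With ``finite_size_correction`` (default) the
    analytic bridge deflation is divided out, iterating the exponent
    estimate to self-consistency, so the curve's log-log slope recovers
    the true fluctuation exponent.
    """
    x = _series_values(series)
    n = x.size
    if n < 64:
        raise ConfigError(f"series too short for rmsf (n={n} < 64)")
    if scales is None:
        scales = log_spaced_scales(8, max(n // 8, 9))
    scales = np.asarray(scales, dtype=int)
    if scales.min() < 4 or scales.max() > n // 4:
        raise ConfigError(
            f"rmsf scales must lie in [4, {n // 4}], got "
            f"[{scales.min()}, {scales.max()}]"
        )
    y = np.cumsum(x - x.mean())
    f2 = np.array([np.mean((y[l:] - y[:-l]) ** 2) for l in scales])
    if f2.max() == 0.0:
        raise DegenerateCurveError("constant series: zero fluctuation at all scales")
    if finite_size_correction:
        log_l = np.log10(scales)
        slope = float(np.polyfit(log_l, 0.5 * np.log10(f2), 1)[0])
        for _ in range(4):
            h = min(max(slope, 0.05), 0.98)
            corr = np.array([_bridge_factor(h, int(l), n) for l in scales])
            slope = float(np.polyfit(log_l, 0.5 * np.log10(f2 / corr), 1)[0])
        f2 = f2 / corr
    return ScalingCurve(scales=scales, values=np.sqrt(f2), kind="rmsf")


def msd_curve(traj: Trajectory, lags=None) -> ScalingCurve:
    """Time-averaged mean squared displacement of a 2D trajectory.

    ``MSD(tau) = mean_t |r(t + tau) - r(t)|^2`` over all overlapping
    origins. Lags must lie in ``[1, n/4]`` (default: every lag up to
    ``n/10``).
    """
    pos = traj.positions
    n = pos.shape[0]
    if lags is None:
        lags = np.arange(1, max(n // 10, 2))
    lags = np.asarray(lags, dtype=int)
    if lags.min() < 1 or lags.max() > n // 4:
        raise ConfigError(
            f"MSD lags must lie in [1, {n // 4}], got "
            f"[{lags.min()}, {lags.max()}]"
        )
    values = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        values[i] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    if values.max() == 0.0:
        raise DegenerateCurveError("stationary trajectory: zero MSD at all lags")
    return ScalingCurve(scales=lags, values=values, kind="msd")


def _dfa_box_rms(profile: np.ndarray, box: int, order: int) -> float:
    """Mean squared detrending residual over non-overlapping boxes,
    averaged over forward and reversed partitions."""
    n = profile.size
    k = n // box
    t = np.arange(box, dtype=float)
    design = np.vander(t, order + 1, increasing=True)
    # pseudo-inverse is shared by every box of this size
    pinv = np.linalg.pinv(design)
    total = 0.0
    for seg in (profile[: k * box], profile[::-1][: k * box]):
        boxes = seg.reshape(k, box)
        coef = boxes @ pinv.T
        resid = boxes - coef @ design.T
        total += np.mean(resid**2)
    return total / 2.0


def dfa_curve(series, box_sizes=None, detrend_order: int = 1) -> ScalingCurve:
    """Detrended fluctuation analysis curve of a 1D series.

    The mean-subtracted series is integrated, partitioned into
    non-overlapping boxes of each size (forward and reversed partitions
    averaged), the per-box polynomial trend of ``detrend_order`` removed,
    and ``F(n)`` taken as the root-mean-square residual.
    """
    x = _series_values(series)
    n = x.size
    if n < 64:
        raise ConfigError(f"series too short for DFA (n={n} < 64)")
    if detrend_order < 0:
        raise ConfigError("detrend_order must be >= 0")
    if box_sizes is None:
        box_sizes = log_spaced_scales(8, max(n // 8, 9))
    box_sizes = np.asarray(box_sizes, dtype=int)
    if box_sizes.max() > n:
        raise ConfigError(
            f"box size {box_sizes.max()} exceeds series length {n}"
        )
    if box_sizes.min() < detrend_order + 2 or box_sizes.max() > n // 4:
        raise ConfigError(
            f"DFA boxes must lie in [{detrend_order + 2}, {n // 4}], got "
            f"[{box_sizes.min()}, {box_sizes.max()}]"
        )
    profile = np.cumsum(x - x.mean())
    values = np.array(
        [np.sqrt(_dfa_box_rms(profile, b, detrend_order)) for b in box_sizes]
    )
    return ScalingCurve(scales=box_sizes, values=values, kind="dfa")


def fit_scaling_exponent(
    curve: ScalingCurve, fit_range: tuple[float, float] | None = None
) -> ScalingFit:
    """OLS slope of log10(F) vs log10(scale), restricted to ``fit_range``.

    Requires at least 4 curve points with strictly positive values inside
    the range. Returns the exponent, the log10 intercept, and R².
    """
    if fit_range is None:
        fit_range = (float(curve.scales[0]), float(curve.scales[-1]))
    lo, hi = fit_range
    mask = (curve.scales >= lo) & (curve.scales <= hi)
    if mask.sum() < 4:
        raise ConfigError(
            f"need >= 4 points in fit range [{lo}, {hi}], have {int(mask.sum())}"
        )
    values = curve.values[mask]
    if np.any(values <= 0):
        raise DegenerateCurveError(
            "nonpositive curve values in fit range; handle the degenerate "
            "curve before fitting"
        )
    res = stats.linregress(np.log10(curve.scales[mask]), np.log10(values))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(float(lo), float(hi)),
        r_squared=float(res.rvalue**2),
        kind=curve.kind,
    )


def correlation_time(
    curve: ScalingCurve,
    fit: ScalingFit,
    dt: float,
    margin: float = 0.05,
    grid_frames: int = 50,
) -> CorrelationTime:
    """Duration of the correlated regime of an rmsf curve.

    Local log-log slopes are evaluated in sliding half-decade windows at
    scales on a ``grid_frames`` grid (50 frames = 25 s at 2 Hz). The
    crossover scale is the largest grid scale such that every local slope
    at smaller scales stays above ``0.5 + margin``; the result in minutes
    is therefore always a multiple of ``grid_frames * dt / 60``.

    If even the first grid scale fails the margin the minimum grid value
    is returned with ``no_correlated_regime`` set.
    """
    if curve.kind != "rmsf":
        raise ConfigError("correlation_time requires an rmsf curve")
    if fit.kind != "rmsf":
        raise ConfigError("fit must come from the same rmsf curve")
    log_l = np.log10(curve.scales)
    safe = np.where(curve.values > 0, curve.values, np.nan)
    log_f = np.log10(safe)
    half = 0.25  # half-decade window: [l / 10^0.25, l * 10^0.25]

    def local_slope(scale: float) -> float:
        lo = max(np.log10(scale) - half, log_l[0])
        hi = min(np.log10(scale) + half, log_l[-1])
        if hi - lo < 1e-9:
            return np.nan
        f_lo = np.interp(lo, log_l, log_f)
        f_hi = np.interp(hi, log_l, log_f)
        return (f_hi - f_lo) / (hi - lo)

    grid = np.arange(grid_frames, int(curve.scales[-1]) + 1, grid_frames)
    if grid.size == 0:
        grid = np.array([grid_frames])
    threshold = 0.5 + margin
    crossover = int(grid[0])
    flag = True
    for g in grid:
        s = local_slope(float(g))
        crossover = int(g)
        if not np.isfinite(s) or s <= threshold:
            break
        flag = False
    minutes = crossover * dt / 60.0
    return CorrelationTime(
        minutes=float(minutes),
        crossover_scale=crossover,
        no_correlated_regime=flag,
    )


def classify_dfa_regime(fit: ScalingFit, input_class: str) -> str | None:
    """Classify a DFA exponent as antipersistent/uncorrelated/persistent.

    ``input_class`` is ``"noise_like"`` (neutral gamma 0.5) or
    ``"brownian_like"`` (neutral gamma 1.5); a ±0.05 band around the
    neutral value reads as uncorrelated. Returns ``None`` (no
    classification) when gamma lies outside (0, 2).
    """
    if fit.kind != "dfa":
        raise ConfigError("classification requires a DFA fit")
    neutral = {"noise_like": 0.5, "brownian_like": 1.5}.get(input_class)
    if neutral is None:
        raise ConfigError(f"unknown input_class {input_class!r}")
    gamma = fit.exponent
    if not (0.0 < gamma < 2.0):
        return None
    if gamma < neutral - 0.05:
        return "antipersistent"
    if gamma > neutral + 0.05:
        return "persistent"
    return "uncorrelated"
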