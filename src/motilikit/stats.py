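"""Nonparametric cohort summaries and tests.

Distributions of per-trajectory metrics fail normality, so cohorts are
reported as median/IQR and compared with rank-based tests: the Wilcoxon
rank-sum (Mann–Whitney) test for two groups and Kruskal–Wallis for
several. The quartile convention is linear interpolation between order
statistics ("type 7"), which the IQR values are sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError

#: The eight per-trajectory metrics of the standard comparison table.
METRIC_COLUMNS = [
    "rmsf_alpha",
    "corr_time_min",
    "msd_beta",
    "dfa_gamma",
    "apen",
    "ir_mm",
    "dr",
    "as_um_s",
]


@dataclass(frozen=True)
class CohortSummary:
    """Per-metric cohort comparison: group medians/IQRs plus test result."""

    metric_name: str
    group_values: dict = field(repr=False)
    medians: dict
    iqrs: dict
    p_value: float
    z_stat: float
    test: str = "wilcoxon"


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigError("median_iqr of an empty list")
    q1, q3 = np.percentile(values, [25, 75])
    return float(np.median(values)), float(q3 - q1)


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Continuity- and tie-corrected normal-approximation Z, signed by
    group a's rank sum relative to its null expectation."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    expect = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.0
    diff = w - expect
    if diff == 0:
        return 0.0
    return float((diff - 0.5 * np.sign(diff)) / np.sqrt(var))


def wilcoxon_rank_sum(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(p_value, z)``.

    ``method="auto"`` uses the exact null distribution for small
    tie-free samples (both n <= 8) and the tie/continuity-corrected
    normal approximation otherwise; ``"exact"``/``"asymptotic"`` force a
    route. Z is always the signed normal-approximation statistic,
    positive when group ``a`` ranks high.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs n >= 2")
    z = _rank_sum_z(a, b)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (not ties and min(a.size, b.size) <= 8) else "asymptotic"
    if method == "exact":
        if ties:
            raise ConfigError("exact method is undefined with ties")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    elif method == "asymptotic":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ConfigError(f"unknown method {method!r}")
    return min(p, 1.0), z


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H test across >= 2 groups; ``(p_value, H)``.

    H carries the tie correction; p comes from the chi-squared reference
    with k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ConfigError("each group needs n >= 2")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 1.0, 0.0  # identical groups: scipy raises on all-equal data
    h, p = sps.kruskal(*groups)
    return float(p), float(h)


def ks_normality(values, alpha: float = 0.05) -> tuple[float, str]:
    """One-sample KS test against a normal with the sample mean/SD.

    Returns ``(p_value, decision)`` where the decision is
    ``"nonparametric_route"`` when normality is rejected at ``alpha`` (or
    when the sample is degenerate), else ``"normal_route"``. Parameters
    are estimated from the data, so the nominal p is conservative in the
    Lilliefors sense.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ConfigError("KS normality test needs n >= 5")
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0, "nonparametric_route"
    _, p = sps.kstest(values, "norm", args=(values.mean(), sd))
    decision = "nonparametric_route" if p < alpha else "normal_route"
    return float(p), decision


def summarize_cohorts(
    metrics: pd.DataFrame,
    group_col: str = "cell_type",
    metric_cols=None,
    groups=None,
) -> list[CohortSummary]:
    """Two-group median/IQR summary plus Wilcoxon test, one per metric.

    ``metrics`` is a per-trajectory table with ``group_col`` and one
    column per metric (default: the eight standard metrics). NaN metric
    values (e.g. undefined cosines) are excluded per metric.
    """
    if metric_cols is None:
        metric_cols = METRIC_COLUMNS
    missing = [m for m in metric_cols if m not in metrics.columns]
    if missing:
        raise ConfigError(f"missing metric column(s): {', '.join(missing)}")
    if group_col not in metrics.columns:
        raise ConfigError(f"missing group column {group_col!r}")
    if groups is None:
        groups = list(pd.unique(metrics[group_col]))
    if len(groups) != 2:
        raise ConfigError(f"need exactly 2 groups, got {groups}")
    out = []
    for metric in metric_cols:
        vals = {
            g: metrics.loc[metrics[group_col] == g, metric].dropna().to_numpy()
            for g in groups
        }
        if any(v.size == 0 for v in vals.values()):
            raise ConfigError(f"empty group for metric {metric!r}")
        med = {g: median_iqr(v)[0] for g, v in vals.items()}
        iqr = {g: median_iqr(v)[1] for g, v in vals.items()}
        p, z = wilcoxon_rank_sum(vals[groups[0]], vals[groups[1]])
        out.append(
            CohortSummary(
                metric_name=metric,
                group_values=vals,
                medians=med,
                iqrs=iqr,
                p_value=p,
                z_stat=z,
            )
        )
    return out


def exact_rank_sum_p(a, b) -> float:
    """Exhaustive-enumeration two-sided rank-sum p (tie-free samples).

    Enumerates all rank assignments; intended as an independent check at
    small n (the number of assignments is C(n1+n2, n1))."""
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < pooled.size:
        raise ConfigError("enumeration requires tie-free data")
    n1, n = a.size, pooled.size
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    extreme = sum(
        1
        for c in combinations(range(1, n + 1), n1)
        if abs(sum(c) - expect) >= abs(w_obs - expect) - 1e-12
    )
    return extreme / comb(n, n1)
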