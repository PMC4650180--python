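"""Winter activity trends: decomposition, group averages, ECDF contrasts.

Each bird-winter's daily activity series is split additively into trend,
seasonal and remainder components; the nonlinear trends are averaged within
reproductive-performance (RP) groups on a common days-since-colony-departure
axis, summarised as empirical cumulative distributions, and compared between
groups with two-sample Kolmogorov-Smirnov tests under Bonferroni correction
(one family = all group pairs x all activity types).  Sex contrasts reuse the
same machinery at the uncorrected level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

ACTIVITIES = ("FLY", "REST", "FORAGE")
_ACT_COL = {"FLY": "p_fly", "REST": "p_rest", "FORAGE": "p_forage"}


@dataclass
class DecompositionResult:
    """Additive decomposition observed = trend + seasonal + remainder.

    The identity holds exactly (to the float arithmetic of the subtraction)
    at every point; ``edge`` flags positions where the centred moving average
    was undefined and the trend was carried from the nearest interior value.
    """

    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    period: int
    edge: np.ndarray

    @property
    def reconstruction(self) -> np.ndarray:
        return self.trend + self.seasonal + self.remainder


@dataclass
class GroupComparison:
    activity: str
    group_a: str
    group_b: str
    ks_statistic: float
    p_value: float
    bonferroni_alpha: float
    significant: bool


def decompose_additive(series, period: int = 7) -> DecompositionResult:
    """Classical additive decomposition with a centred moving-average trend.

    The trend is the centred moving average of window ``period`` (a 2 x period
    average when the period is even); the seasonal component is the
    period-position means of the detrended series, centred to zero mean; the
    remainder is what is left.  Edge points where the moving average is
    undefined carry the nearest defined trend value and are flagged.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = len(y)
    if period < 2:
        raise ValueError("period must be >= 2")
    if n < 2 * period:
        raise ValueError(f"series length {n} < 2 * period = {2 * period}")

    if period % 2:  # simple centred MA
        kernel = np.full(period, 1.0 / period)
        half = period // 2
    else:  # 2 x period MA: half weight on the two outermost points
        kernel = np.concatenate([[0.5], np.ones(period - 1), [0.5]]) / period
        half = period // 2
    valid = np.convolve(y, kernel, mode="valid")
    trend = np.full(n, np.nan)
    trend[half : half + len(valid)] = valid
    edge = np.isnan(trend)
    # nearest-value extrapolation at the edges
    trend[:half] = trend[half]
    last = half + len(valid) - 1
    trend[last + 1 :] = trend[last]

    detrended = y - trend
    positions = np.arange(n) % period
    seasonal_means = np.array(
        [np.nanmean(detrended[~edge][positions[~edge] == p]) if
         np.any(positions[~edge] == p) else 0.0
         for p in range(period)]
    )
    seasonal_means -= seasonal_means.mean()
    seasonal = seasonal_means[positions]
    remainder = y - trend - seasonal
    return DecompositionResult(
        observed=y,
        trend=trend,
        seasonal=seasonal,
        remainder=remainder,
        period=period,
        edge=edge,
    )


def _winter_day(profiles: pd.DataFrame) -> pd.DataFrame:
    """Attach a per-bird days-since-first-profile (colony departure) column."""
    out = profiles.copy()
    first = out.groupby("bird_id")["date"].transform("min")
    out["winter_day"] = (out["date"] - first).dt.days
    return out


def bird_trends(
    profiles: pd.DataFrame, activity: str, period: int = 7
) -> dict[str, pd.Series]:
    """Per-bird trend component of one activity, indexed by winter day."""
    col = _ACT_COL[activity]
    out: dict[str, pd.Series] = {}
    for bird, sub in _winter_day(profiles).groupby("bird_id"):
        sub = sub.sort_values("winter_day")
        vals = sub[col].to_numpy(float)
        if period >= 2 and len(vals) >= 2 * period:
            tr = decompose_additive(vals, period).trend
        else:  # too short (or seasonal term disabled): use the raw series
            tr = vals
        out[str(bird)] = pd.Series(tr, index=sub["winter_day"].to_numpy())
    return out


def group_mean_trend(
    profiles: pd.DataFrame,
    labels: Mapping[str, str],
    activity: str,
    period: int = 7,
) -> pd.DataFrame:
    """Pointwise group-mean trend over the common winter span.

    Winters are aligned on days since colony departure and truncated to the
    shortest span common to all birds, avoiding composition bias where late
    winters thin out.  Returns columns ``winter_day``, one mean per group and
    per-day bird counts.
    """
    trends = bird_trends(profiles, activity, period)
    if not trends:
        raise ValueError("no profiles supplied")
    span = min(int(s.index.max()) for s in trends.values())
    days = np.arange(span + 1)
    groups: dict[str, list[np.ndarray]] = {}
    for bird, tr in trends.items():
        lab = labels.get(bird)
        if lab is None:
            continue
        aligned = tr.reindex(days)
        groups.setdefault(lab, []).append(aligned.to_numpy())
    result = pd.DataFrame({"winter_day": days})
    for lab in sorted(groups):
        stack = np.vstack(groups[lab])
        if stack.shape[0] == 0:
            warnings.warn(f"group {lab} empty; omitted")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result[f"mean_{lab}"] = np.nanmean(stack, axis=0)
            result[f"n_{lab}"] = (~np.isnan(stack)).sum(axis=0)
    return result


def ecdf_by_group(values_by_group: Mapping[str, np.ndarray]) -> dict[str, ECDF]:
    """Right-continuous empirical CDF per group, evaluable anywhere."""
    out = {}
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has no values")
        out[g] = ECDF(vals)
    return out


def compare_groups(
    values: Mapping[str, Mapping[str, np.ndarray]],
    alpha: float = 0.01,
    method: str = "auto",
) -> list[GroupComparison]:
    """Pairwise two-sample KS tests with Bonferroni correction.

    ``values`` maps activity -> group -> sample.  The correction divides
    ``alpha`` by the family size m = (#group pairs) x (#activities); a
    comparison is significant iff p < alpha / m.  Identical constant samples
    are reported as D = 0, p = 1.
    """
    activities = list(values)
    if not activities:
        raise ValueError("no activities supplied")
    group_sets = [tuple(sorted(values[a])) for a in activities]
    if len(set(group_sets)) != 1:
        raise ValueError("all activities must share the same groups")
    groups = group_sets[0]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(groups, 2))
    m = len(pairs) * len(activities)
    corrected = alpha / m
    out = []
    for act in activities:
        for a, b in pairs:
            xa = np.asarray(values[act][a], dtype=float)
            xb = np.asarray(values[act][b], dtype=float)
            xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(f"group {a!r}/{b!r} too small for a KS test")
            if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
                d, p = 0.0, 1.0
            else:
                res = stats.ks_2samp(xa, xb, method=method)
                d, p = float(res.statistic), float(res.pvalue)
            out.append(
                GroupComparison(
                    activity=act,
                    group_a=a,
                    group_b=b,
                    ks_statistic=d,
                    p_value=p,
                    bonferroni_alpha=corrected,
                    significant=p < corrected,
                )
            )
    return out


def sex_contrasts(
    profiles: pd.DataFrame,
    sexes: Mapping[str, str],
    period: int = 7,
    method: str = "auto",
) -> dict[str, tuple[float, float]]:
    """Raw (uncorrected) KS contrasts of female vs male mean activity trends.

    Returns ``{activity: (D, p)}`` using the pooled group-mean trend values,
    mirroring the RP contrasts but reported at the uncorrected level.
    """
    out = {}
    for act in ACTIVITIES:
        gm = group_mean_trend(profiles, sexes, act, period)
        cols = [c for c in gm.columns if c.startswith("mean_")]
        if len(cols) != 2:
            raise ValueError("need exactly two sexes present")
        a = gm[cols[0]].dropna().to_numpy()
        b = gm[cols[1]].dropna().to_numpy()
        res = stats.ks_2samp(a, b, method=method)
        out[act] = (float(res.statistic), float(res.pvalue))
    return out


def pooled_group_trend_values(
    profiles: pd.DataFrame,
    labels: Mapping[str, str],
    period: int = 7,
) -> dict[str, dict[str, np.ndarray]]:
    """Group-mean trend values pooled over winter days, per activity.

    This is the input to :func:`ecdf_by_group` and :func:`compare_groups`:
    the distribution, over aligned winter days, of each group's mean trend.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for act in ACTIVITIES:
        gm = group_mean_trend(profiles, labels, act, period)
        per_group = {}
        for c in gm.columns:
            if c.startswith("mean_"):
                per_group[c[len("mean_"):]] = gm[c].dropna().to_numpy()
        out[act] = per_group
    return out


def plot_ecdf_panels(values, path=None):
    """Fig-2-style ECDF panels (one per activity, one curve per RP group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acts = list(values)
    fig, axes = plt.subplots(1, len(acts), figsize=(4 * len(acts), 3.2))
    axes = np.atleast_1d(axes)
    colors = {"SUCCESS": "tab:blue", "FAIL": "tab:red", "SKIP": "black"}
    for ax, act in zip(axes, acts):
        for g, vals in values[act].items():
            e = ECDF(np.asarray(vals, float))
            ax.step(e.x, e.y, where="post", label=g, color=colors.get(g))
        ax.set_title(act.lower())
        ax.set_xlabel("mean trend value")
        ax.set_ylabel("ECDF")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
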