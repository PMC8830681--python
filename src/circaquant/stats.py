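"""Per-cell intensity statistics and two-group inference.

Implements the study's inference recipe for comparing uptake between
conditions or timepoints: intensities below the background signal are
discarded, survivors are log10-transformed, Tukey-fence outliers are
removed per timepoint, and each contrast is judged jointly by a Welch
two-sample t-test and Hedges' g — a small effect negates a significant
p-value, a large effect confirms it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PreprocessResult",
    "WelchResult",
    "HedgesResult",
    "ComparisonResult",
    "preprocess_intensities",
    "welch_test",
    "hedges_g",
    "effect_class",
    "joint_decision",
    "compare_groups",
    "timepoint_summary",
    "iqr_fences",
]

EFFECT_THRESHOLDS = {"small": 0.2, "medium": 0.5, "large": 0.8}


@dataclass
class PreprocessResult:
    """Filtered table plus an audit trail of what was removed where."""

    kept: pd.DataFrame
    removed: pd.DataFrame
    n_below_threshold: int
    n_iqr_removed: int
    skipped_timepoints: list = field(default_factory=list)


def iqr_fences(values) -> tuple[float, float]:
    """Tukey fences [Q1 - 1.5*IQR, Q3 + 1.5*IQR], linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def preprocess_intensities(
    table: pd.DataFrame,
    background_signal: float = 0.0,
    *,
    value_col: str = "value",
    time_col: str = "time_ps",
    iqr_multiplier: float = 1.5,
) -> PreprocessResult:
    """Threshold, log10-transform and IQR-filter per-cell intensities.

    Order matters and is single-pass: (1) drop values at or below the
    background signal, (2) log10-transform survivors into ``log10_value``,
    (3) per timepoint, drop logged values outside the Tukey fences computed
    once on that timepoint's logged values. Timepoints left with fewer than
    3 values after thresholding are flagged and skip the IQR step.
    """
    df = table.copy()
    below = df[value_col] <= background_signal
    removed_thr = df[below].copy()
    removed_thr["removal_reason"] = "below_threshold"
    df = df[~below].copy()
    df["log10_value"] = np.log10(df[value_col])

    keep_parts, removed_parts, skipped = [], [removed_thr], []
    for t, grp in df.groupby(time_col, sort=True):
        if len(grp) < 3:
            skipped.append(t)
            keep_parts.append(grp)
            continue
        q1, q3 = np.percentile(grp["log10_value"], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        out = (grp["log10_value"] < lo) | (grp["log10_value"] > hi)
        bad = grp[out].copy()
        bad["removal_reason"] = "iqr_outlier"
        removed_parts.append(bad)
        keep_parts.append(grp[~out])

    kept = (pd.concat(keep_parts).sort_index()
            if keep_parts else df.iloc[0:0].assign(log10_value=[]))
    removed = pd.concat(removed_parts).sort_index()
    return PreprocessResult(
        kept=kept,
        removed=removed,
        n_below_threshold=int(below.sum()),
        n_iqr_removed=int(len(removed) - below.sum()),
        skipped_timepoints=skipped,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degenerate inputs (both variances zero) return p=1 for equal means and
    p=0, flagged, for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0, degenerate=True)
        return WelchResult(np.inf if x.mean() > y.mean() else -np.inf,
                           float(len(x) + len(y) - 2), 0.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    n1, n2 = len(x), len(y)
    se1, se2 = v1 / n1, v2 / n2
    denom = se1**2 / (n1 - 1) + se2**2 / (n2 - 1)
    # denom can underflow to 0 for subnormal variances; fall back to pooled df
    nu = (se1 + se2) ** 2 / denom if denom > 0 else float(n1 + n2 - 2)
    return WelchResult(float(res.statistic), float(nu), float(res.pvalue))


@dataclass(frozen=True)
class HedgesResult:
    g: float
    effect_class: str


def effect_class(g: float) -> str:
    """Effect-size band on |g|: negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large."""
    a = abs(g)
    if a >= EFFECT_THRESHOLDS["large"]:
        return "large"
    if a >= EFFECT_THRESHOLDS["medium"]:
        return "medium"
    if a >= EFFECT_THRESHOLDS["small"]:
        return "small"
    return "negligible"


def hedges_g(x, y) -> HedgesResult:
    """Signed Hedges' g: pooled-SD Cohen's d with small-sample bias correction.

    g = d * (1 - 3 / (4*(n1+n2) - 9)) with d = (mean(x) - mean(y)) / s_p and
    s_p the pooled standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled variance is zero; Hedges' g undefined")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    g = float(d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)))
    return HedgesResult(g=g, effect_class=effect_class(g))


def joint_decision(p: float, g: float, alpha: float = 0.05, g_min: float = 0.5) -> bool:
    """Significant only when the p-value AND the effect size both clear their gates."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    return bool(p < alpha and abs(g) >= g_min)


@dataclass(frozen=True)
class ComparisonResult:
    label_x: str
    label_y: str
    n_x: int
    n_y: int
    t: float
    df: float
    p: float
    g: float
    effect_class: str
    significant: bool
    alpha: float
    g_min: float


def compare_groups(
    x, y,
    label_x: str = "x",
    label_y: str = "y",
    alpha: float = 0.05,
    g_min: float = 0.5,
) -> ComparisonResult:
    """Full two-group contrast: Welch t, Hedges' g, and the joint verdict."""
    w = welch_test(x, y)
    h = hedges_g(x, y)
    return ComparisonResult(
        label_x=label_x, label_y=label_y, n_x=len(x), n_y=len(y),
        t=w.t, df=w.df, p=w.p, g=h.g, effect_class=h.effect_class,
        significant=joint_decision(w.p, h.g, alpha, g_min),
        alpha=alpha, g_min=g_min,
    )


def timepoint_summary(
    table: pd.DataFrame,
    *,
    value_col: str = "log10_value",
    time_col: str = "time_ps",
    replicate_col: str = "replicate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-timepoint replicate means and their cross-replicate average.

    Returns (replicate_means, timepoint_means); the replicate-resolved
    table is retained because the proteoglycan analysis fits all
    replicates while the phagocytosis analysis fits the averages.
    """
    rep_means = (
        table.groupby([time_col, replicate_col])[value_col]
        .mean().rename("value").reset_index()
    )
    tp_means = (
        rep_means.groupby(time_col)["value"].mean().rename("value").reset_index()
    )
    return rep_means, tp_means
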