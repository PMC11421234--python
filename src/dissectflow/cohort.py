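"""Longitudinal cohort analysis: aortic growth rates, interval changes in
hemodynamic parameters, and the correlation / group-comparison statistics.

Growth rate is the absolute change in maximal descending-aorta diameter per
unit time (mm/year, year = 365.25 days); rapid growth is strictly greater
than 3 mm/year.  A relative growth rate (%/year of baseline diameter) is also
emitted.  Records with a scan interval under 120 days are excluded (the
longitudinal inclusion rule) with a logged reason.

Interval changes are expressed both as raw percent change and as percent per
year; correlations with growth use Spearman's rho with average ranks, a
t-distribution p-value for n > 10 and an exact permutation p-value for
n <= 10.  Group comparisons gate an independent t-test on Shapiro-Wilk
normality of both groups (alpha 0.05), otherwise a Mann-Whitney U-test;
categorical variables use a chi-square contingency test.  No multiple-testing
correction is applied by default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthRecord",
    "IntervalChange",
    "CorrelationResult",
    "GroupComparison",
    "compute_growth_rate",
    "compute_interval_change",
    "spearman",
    "correlate_with_growth",
    "compare_groups",
    "adjust_bh",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
MIN_INTERVAL_DAYS = 120.0
RAPID_GROWTH_MM_PER_YEAR = 3.0


@dataclass(frozen=True)
class GrowthRecord:
    """Per-patient paired-scan diameters and derived growth quantities."""

    patient_id: str
    subgroup: str  # "rTAAD" | "dnTBAD"
    baseline_diameter: float  # mm
    followup_diameter: float  # mm
    interval_days: float
    growth_rate: float  # mm/year
    relative_growth_rate: float  # %/year
    rapid: bool


@dataclass(frozen=True)
class IntervalChange:
    parameter: str
    baseline: float
    followup: float
    delta_pct: float
    delta_pct_per_year: float


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    rho: float
    p_value: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]


def compute_growth_rate(
    baseline_diameter: float,
    followup_diameter: float,
    interval_days: float,
    patient_id: str = "",
    subgroup: str = "",
) -> GrowthRecord | None:
    """Growth record, or None when the interval fails the 120-day rule."""
    if baseline_diameter <= 0:
        raise ValueError("baseline diameter must be positive")
    if interval_days < MIN_INTERVAL_DAYS:
        logger.info(
            "excluding patient %s: interval %.0f days < %.0f-day inclusion minimum",
            patient_id, interval_days, MIN_INTERVAL_DAYS,
        )
        return None
    years = interval_days / DAYS_PER_YEAR
    growth = (followup_diameter - baseline_diameter) / years
    relative = 100.0 * (followup_diameter - baseline_diameter) / baseline_diameter / years
    return GrowthRecord(
        patient_id=patient_id,
        subgroup=subgroup,
        baseline_diameter=baseline_diameter,
        followup_diameter=followup_diameter,
        interval_days=interval_days,
        growth_rate=growth,
        relative_growth_rate=relative,
        rapid=growth > RAPID_GROWTH_MM_PER_YEAR,
    )


def compute_interval_change(
    baseline: dict[str, float],
    followup: dict[str, float],
    interval_days: float,
) -> dict[str, IntervalChange]:
    """Percent and percent-per-year change for each shared parameter.

    Parameters with zero baseline are recorded with NaN changes (undefined).
    """
    if set(baseline) != set(followup):
        raise ValueError("baseline and follow-up parameter sets differ")
    years = interval_days / DAYS_PER_YEAR
    out: dict[str, IntervalChange] = {}
    for name in baseline:
        b, f = baseline[name], followup[name]
        if b == 0 or not np.isfinite(b) or not np.isfinite(f):
            logger.info("change in %s undefined (baseline %.3g)", name, b)
            pct = pct_year = float("nan")
        else:
            pct = 100.0 * (f - b) / b
            pct_year = pct / years
        out[name] = IntervalChange(name, b, f, pct, pct_year)
    return out


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho, n <= 10.

    Enumerates all n! orderings of one rank vector; with ties the statistic is
    Pearson correlation of ranks, which reduces to an affine function of
    sum(rx * ry_perm), so only that inner product is computed per permutation.
    """
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return float("nan")
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    tol = 1e-12

    def flush(chunk_perms: list[tuple[int, ...]]) -> tuple[int, int]:
        perm = np.array(chunk_perms)
        rhos = (ryc[perm] @ rxc) / denom
        return int((np.abs(rhos) >= abs(rho_obs) - tol).sum()), len(chunk_perms)

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == 200_000:
            c, t = flush(chunk)
            count += c
            total += t
            chunk = []
    if chunk:
        c, t = flush(chunk)
        count += c
        total += t
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman correlation with average ranks and a size-adapted p-value.

    For n > 10 the p-value uses the t-distribution approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))``; for n <= 10 it is an exact
    permutation p-value.  Constant input yields an undefined result
    (``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult("", float("nan"), float("nan"), n, defined=False)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("", float("nan"), float("nan"), n, defined=False)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_permutation_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult("", rho, p, n)


def correlate_with_growth(
    cohort: pd.DataFrame,
    parameter: str,
    subgroup: str | None = None,
    normalization: str = "percent_per_year",
    growth_column: str = "growth_rate",
) -> CorrelationResult:
    """Spearman correlation of a parameter's interval change with growth rate.

    ``cohort`` holds one row per patient with ``{parameter}_baseline`` and
    ``{parameter}_followup`` columns (plus ``interval_days`` and the growth
    column).  ``normalization`` selects "percent" (raw Delta%) or
    "percent_per_year" (Delta% divided by the scan interval in years).
    Missing values are dropped pairwise; at least 5 pairs are required.
    """
    if normalization not in ("percent", "percent_per_year"):
        raise ValueError(f"unknown normalization {normalization!r}")
    df = cohort if subgroup is None else cohort[cohort["subgroup"] == subgroup]
    base = df[f"{parameter}_baseline"].to_numpy(dtype=float)
    follow = df[f"{parameter}_followup"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (follow - base) / base
    delta[base == 0] = np.nan
    if normalization == "percent_per_year":
        delta = delta / (df["interval_days"].to_numpy(dtype=float) / DAYS_PER_YEAR)
    growth = df[growth_column].to_numpy(dtype=float)
    ok = np.isfinite(delta) & np.isfinite(growth)
    if ok.sum() < 5:
        raise ValueError(
            f"only {int(ok.sum())} complete pairs for {parameter}; need >= 5"
        )
    res = spearman(delta[ok], growth[ok])
    return CorrelationResult(parameter, res.rho, res.p_value, res.n, res.defined)


def _is_degenerate(a: np.ndarray) -> bool:
    return np.ptp(a) == 0


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    variable: str = "",
    categorical: bool = False,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Continuous data: Shapiro-Wilk on each group at alpha 0.05 decides between
    an independent t-test (both normal) and a Mann-Whitney U-test; degenerate
    (constant) groups skip the normality test and take the nonparametric
    branch.  ``alternative`` supports one-sided tests ("greater": a > b),
    applied to whichever branch runs.  Categorical data: ``a`` and ``b`` are
    per-group count vectors forming a contingency table for a chi-square test.
    """
    if categorical:
        table = np.array([a, b])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(
            variable, "chi-square", float(chi2), float(p),
            (int(np.sum(a)), int(np.sum(b))),
        )
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    if _is_degenerate(a) or _is_degenerate(b):
        normal = False
    else:
        normal = (
            stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        )
    if normal:
        res = stats.ttest_ind(a, b, alternative=alternative)
        name = "t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        name = "mann-whitney-u" if alternative == "two-sided" else "mann-whitney-u-1tail"
    return GroupComparison(
        variable, name, float(res.statistic), float(res.pvalue), (len(a), len(b))
    )


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out
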