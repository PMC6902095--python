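"""Cohort-level statistics: descriptives, rank tests, stratification,
ECDFs, paired pre/post therapy analysis, and the severity-score association.

Conventions
-----------
* All p-values are two-sided; the significance threshold is fixed at 0.01.
* Mann-Whitney U uses midranks for ties; the two-sided p comes from exact
  enumeration when ``max(n, m) <= 8`` and there are no ties, otherwise from
  the normal approximation with tie correction and continuity correction.
  The reported ``U`` is ``min(U_x, U_y)``.
* The two-sample Kolmogorov-Smirnov ``D`` keeps its sign: it is the value
  of ``F_x - F_y`` at the point maximizing ``|F_x - F_y|`` (first minus
  second).  ``alpha`` is the asymptotic Kolmogorov tail probability at
  ``|D| * sqrt(n*m/(n+m))`` - a p-value, despite the name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "Descriptives",
    "TestResult",
    "ComparisonReport",
    "TherapyReport",
    "PanssReport",
    "SIGNIFICANCE_LEVEL",
    "EXACT_MW_MAX_N",
    "descriptive",
    "mann_whitney",
    "ks_two_sample",
    "compare_groups",
    "stratify_by_birth_year",
    "ecdf",
    "paired_therapy_analysis",
    "panss_association",
]

SIGNIFICANCE_LEVEL = 0.01

#: Largest per-group size for which the exact Mann-Whitney null is enumerated.
EXACT_MW_MAX_N = 8

#: Baseline windows (pg/ng) for the paired-therapy subgroup deltas.
LOW_BASELINE_MAX = 12.0
HIGH_BASELINE_MIN = 25.0

#: Default content threshold (pg/ng) for the severity-score dichotomization.
PANSS_CONTENT_THRESHOLD = 20.0


@dataclass(frozen=True)
class Descriptives:
    """Per-group summary: n, mean, sample SD (divisor n-1), range, median, CV."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    cv: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "median": self.median,
            "cv": self.cv,
        }

    def rounded(self, cv_dp: int = 2, content_dp: int = 1) -> dict:
        """Report-time rounding; internal values are never rounded."""
        return {
            "n": self.n,
            "mean": round(self.mean, content_dp),
            "sd": round(self.sd, content_dp),
            "min": round(self.min, content_dp),
            "max": round(self.max, content_dp),
            "median": round(self.median, content_dp),
            "cv": round(self.cv, cv_dp),
        }


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample test."""

    test: str  # "mann_whitney" | "ks_two_sample"
    p: float
    U: float | None = None
    D: float | None = None
    alpha: float | None = None

    @property
    def significant(self) -> bool:
        return self.p <= SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        d: dict = {"test": self.test, "p": self.p, "significant": self.significant}
        if self.U is not None:
            d["U"] = self.U
        if self.D is not None:
            d["D"] = self.D
        if self.alpha is not None:
            d["alpha"] = self.alpha
        return d


def descriptive(values: Iterable[float]) -> Descriptives:
    """Compute descriptives; for n = 1, SD and CV are defined as zero."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    n = int(arr.size)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return Descriptives(
        n=n,
        mean=mean,
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        median=float(np.median(arr)),
        cv=sd / mean if mean != 0 else 0.0,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_mw_p(n: int, m: int, u_x: float) -> float:
    """Two-sided p by full enumeration of the C(n+m, n) rank assignments.

    Valid only without ties, where U_x takes integer values.
    """
    total = n + m
    ranks = np.arange(1, total + 1)
    offset = n * (n + 1) / 2.0
    us = [sum(c) - offset for c in combinations(ranks, n)]
    us = np.asarray(us)
    n_comb = len(us)
    p_le = np.count_nonzero(us <= u_x + 1e-9) / n_comb
    p_ge = np.count_nonzero(us >= u_x - 1e-9) / n_comb
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Returns ``U = min(U_x, U_y)`` and a two-sided p-value (exact enumeration
    for small untied samples, tie- and continuity-corrected normal
    approximation otherwise).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x
    u_min = min(u_x, u_y)

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(n, m) <= EXACT_MW_MAX_N:
        p = _exact_mw_p(n, m, u_x)
    else:
        total = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (total * (total - 1)) if total > 1 else 0.0
        var = n * m / 12.0 * (total + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(u_x - n * m / 2.0) - 0.5, 0.0) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(z)
    return TestResult(test="mann_whitney", p=min(p, 1.0), U=float(u_min))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with a signed D.

    ``D`` is ``F_x - F_y`` evaluated where ``|F_x - F_y|`` is maximal;
    ``alpha`` is the asymptotic Kolmogorov tail probability of
    ``|D| * sqrt(n*m/(n+m))`` and is reported as ``p`` as well.
    """
    x = np.sort(np.asarray(list(x), dtype=float))
    y = np.sort(np.asarray(list(y), dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    grid = np.unique(np.concatenate([x, y]))
    f_x = np.searchsorted(x, grid, side="right") / n
    f_y = np.searchsorted(y, grid, side="right") / m
    diff = f_x - f_y
    # ties in |diff| break toward the smallest evaluation point
    k = int(np.argmax(np.abs(diff)))
    d_signed = float(diff[k])
    stat = abs(d_signed) * math.sqrt(n * m / (n + m))
    alpha = float(special.kolmogorov(stat))
    return TestResult(test="ks_two_sample", p=alpha, D=d_signed, alpha=alpha)


@dataclass
class ComparisonReport:
    """Pairwise group comparisons: descriptives and both rank tests."""

    pairs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"pairs": self.pairs}


def compare_groups(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    value_column: str = "content",
    group_column: str = "group",
) -> ComparisonReport:
    """Run Mann-Whitney and KS for each named group pair, with descriptives."""
    known = set(cohort[group_column].unique())
    report = ComparisonReport()
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in known:
                raise KeyError(f"unknown group label {g!r}")
        x = cohort.loc[cohort[group_column] == g1, value_column].to_numpy(float)
        y = cohort.loc[cohort[group_column] == g2, value_column].to_numpy(float)
        report.pairs.append(
            {
                "group_1": g1,
                "group_2": g2,
                "descriptives_1": descriptive(x).to_dict(),
                "descriptives_2": descriptive(y).to_dict(),
                "mann_whitney": mann_whitney(x, y).to_dict(),
                "ks": ks_two_sample(x, y).to_dict(),
            }
        )
    return report


def stratify_by_birth_year(
    cohort: pd.DataFrame, cut_year: int = 1990, year_column: str = "birth_year"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (older, younger) strata; year >= cut_year is younger.

    The partition is exhaustive and disjoint; missing birth years raise.
    """
    if year_column not in cohort.columns or cohort[year_column].isna().any():
        raise ValueError("birth years are required for stratification")
    younger = cohort[cohort[year_column] >= cut_year]
    older = cohort[cohort[year_column] < cut_year]
    return older, younger


def ecdf(values: Iterable[float]) -> pd.DataFrame:
    """Right-continuous empirical CDF as (value, cumulative_fraction) rows
    over the distinct sorted values; the final fraction is 1."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(arr)
    frac = np.searchsorted(arr, uniq, side="right") / arr.size
    return pd.DataFrame({"value": uniq, "cumulative_fraction": frac})


@dataclass
class TherapyReport:
    cv_pre: float
    cv_post: float
    delta_on_pre_slope: float
    low_baseline_delta_mean: float
    high_baseline_delta_mean: float
    n: int
    n_low_baseline: int
    n_high_baseline: int
    mw: TestResult
    ks: TestResult

    def to_dict(self) -> dict:
        return {
            "cv_pre": self.cv_pre,
            "cv_post": self.cv_post,
            "delta_on_pre_slope": self.delta_on_pre_slope,
            "low_baseline_delta_mean": self.low_baseline_delta_mean,
            "high_baseline_delta_mean": self.high_baseline_delta_mean,
            "n": self.n,
            "n_low_baseline": self.n_low_baseline,
            "n_high_baseline": self.n_high_baseline,
            "mann_whitney": self.mw.to_dict(),
            "ks": self.ks.to_dict(),
        }


def paired_therapy_analysis(
    pre: Sequence[float],
    post: Sequence[float],
    low_baseline_max: float = LOW_BASELINE_MAX,
    high_baseline_min: float = HIGH_BASELINE_MIN,
) -> TherapyReport:
    """Paired baseline/follow-up analysis.

    Reports the CV of each occasion, the OLS slope of (post - pre) on pre (a
    regression-to-the-mean summary), mean deltas in the low (<= 12 pg/ng)
    and high (>= 25 pg/ng) baseline windows, and unpaired Mann-Whitney and
    KS comparisons of the two occasions.
    """
    pre = np.asarray(list(pre), dtype=float)
    post = np.asarray(list(post), dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    delta = post - pre
    slope = float(np.polyfit(pre, delta, 1)[0]) if np.ptp(pre) > 0 else 0.0
    low_mask = pre <= low_baseline_max
    high_mask = pre >= high_baseline_min
    return TherapyReport(
        cv_pre=descriptive(pre).cv,
        cv_post=descriptive(post).cv,
        delta_on_pre_slope=slope,
        low_baseline_delta_mean=float(delta[low_mask].mean()) if low_mask.any() else float("nan"),
        high_baseline_delta_mean=float(delta[high_mask].mean()) if high_mask.any() else float("nan"),
        n=int(pre.size),
        n_low_baseline=int(low_mask.sum()),
        n_high_baseline=int(high_mask.sum()),
        mw=mann_whitney(pre, post),
        ks=ks_two_sample(pre, post),
    )


@dataclass
class PanssReport:
    ols_slope: float
    ols_intercept: float
    pearson_r: float
    threshold: float
    subgroup_low_desc: Descriptives  # content < threshold ("subgroup I")
    subgroup_high_desc: Descriptives  # content >= threshold ("subgroup II")
    mw: TestResult

    def to_dict(self) -> dict:
        return {
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "pearson_r": self.pearson_r,
            "threshold": self.threshold,
            "subgroup_low": self.subgroup_low_desc.to_dict(),
            "subgroup_high": self.subgroup_high_desc.to_dict(),
            "mann_whitney": self.mw.to_dict(),
        }


def panss_association(
    content: Sequence[float],
    panss: Sequence[float],
    threshold: float = PANSS_CONTENT_THRESHOLD,
) -> PanssReport:
    """Severity-score association: OLS of the score on content, Pearson r,
    and a dichotomized comparison of scores below vs at/above the content
    threshold (Mann-Whitney)."""
    content = np.asarray(list(content), dtype=float)
    panss = np.asarray(list(panss), dtype=float)
    if content.size != panss.size:
        raise ValueError("content and panss must have equal length")
    if content.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(content) == 0:
        raise ValueError("content has zero variance")
    slope, intercept = np.polyfit(content, panss, 1)
    r = float(np.corrcoef(content, panss)[0, 1]) if np.ptp(panss) > 0 else 0.0
    low_mask = content < threshold
    high_mask = ~low_mask
    if not low_mask.any() or not high_mask.any():
        raise ValueError("dichotomization produced an empty subgroup")
    return PanssReport(
        ols_slope=float(slope),
        ols_intercept=float(intercept),
        pearson_r=r,
        threshold=threshold,
        subgroup_low_desc=descriptive(panss[low_mask]),
        subgroup_high_desc=descriptive(panss[high_mask]),
        mw=mann_whitney(panss[low_mask], panss[high_mask]),
    )
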