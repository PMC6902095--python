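"""Multi-repeat analysis across brain regions.

Partitions a per-region satellite-content vector into two subgroups by an
exhaustive 1-D two-means threshold scan, checks the near-constancy of the
rDNA repeat, and measures the correlation between repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import mann_whitney

__all__ = [
    "partition_bimodal",
    "constancy_check",
    "repeat_correlation",
    "analyze_panel",
    "RDNA_CV_TOLERANCE",
]

#: Default relative tolerance for the rDNA constancy check.
RDNA_CV_TOLERANCE = 0.05


def partition_bimodal(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Optimal two-subset split of a 1-D sample.

    Scans all n-1 thresholds between consecutive order statistics and picks
    the split minimizing the total within-subset sum of squares (both
    subsets nonempty).  The optimum of the unrestricted two-subset problem
    is always contiguous in sorted order, so the scan is exhaustive.

    Returns ``(labels, low_mean, high_mean)`` with labels ``"low"``/``"high"``
    aligned to the input order and ``low_mean < high_mean``.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 4:
        raise ValueError("need at least 4 values to partition")
    if np.ptp(arr) == 0:
        raise ValueError("all values equal: no separation")
    order = np.argsort(arr, kind="stable")
    s = arr[order]
    best_k, best_ss = None, np.inf
    for k in range(1, n):
        lo, hi = s[:k], s[k:]
        ss = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        if ss < best_ss - 1e-12:
            best_ss, best_k = ss, k
    labels = np.empty(n, dtype=object)
    labels[order[:best_k]] = "low"
    labels[order[best_k:]] = "high"
    return labels, float(s[:best_k].mean()), float(s[best_k:].mean())


def constancy_check(values: Sequence[float], rel_tol: float = RDNA_CV_TOLERANCE) -> tuple[bool, float]:
    """Pass iff the coefficient of variation (sample SD / mean) is <= rel_tol."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    cv = float(arr.std(ddof=1) / arr.mean()) if arr.mean() != 0 else float("inf")
    return cv <= rel_tol, cv


def repeat_correlation(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Pearson r and Spearman rho between two aligned repeat-content vectors."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    pearson = float(np.corrcoef(x, y)[0, 1])
    rho = float(stats.spearmanr(x, y).statistic)
    return {"pearson_r": pearson, "spearman_rho": rho}


def analyze_panel(
    panel: pd.DataFrame,
    rdna_tol: float = RDNA_CV_TOLERANCE,
    ratio_dp: int = 1,
) -> dict:
    """Full panel report: bimodal partition of the satellite content with the
    subgroup mean ratio (rounded only in the report), an rDNA constancy
    check, a Mann-Whitney p between the subgroups, and the satellite vs
    telomere-repeat correlation.

    Expects columns ``region, satIII, rdna, tr``.
    """
    for col in ("region", "satIII", "rdna", "tr"):
        if col not in panel.columns:
            raise ValueError(f"panel is missing column {col!r}")
    sat = panel["satIII"].to_numpy(float)
    labels, low_mean, high_mean = partition_bimodal(sat)
    low_vals = sat[labels == "low"]
    high_vals = sat[labels == "high"]
    passed, rdna_cv = constancy_check(panel["rdna"].to_numpy(float), rel_tol=rdna_tol)
    corr = repeat_correlation(sat, panel["tr"].to_numpy(float))
    return {
        "regions": list(panel["region"]),
        "subgroup": list(labels),
        "low_mean": low_mean,
        "high_mean": high_mean,
        "ratio_high_to_low": round(high_mean / low_mean, ratio_dp),
        "n_low": int(low_vals.size),
        "n_high": int(high_vals.size),
        "subgroup_mw": mann_whitney(low_vals, high_vals).to_dict(),
        "rdna_constant": bool(passed),
        "rdna_cv": rdna_cv,
        "satIII_tr_correlation": corr,
    }
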