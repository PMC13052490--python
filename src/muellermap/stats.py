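"""Per-sample summaries and normality-gated two-group comparisons.

Each sample contributes one value per parameter — the median over its masked
tissue pixels (mean and standard deviation are carried alongside but the
median is the tested descriptor).  Two comparisons are run for every
parameter: pooled EDS (cEDS + hEDS) versus healthy controls, and cEDS versus
hEDS.  The test is chosen per comparison by a Shapiro-Wilk normality gate:
Welch's t-test when both groups look normal, the Mann-Whitney U test
otherwise.  Two-tailed, alpha = 0.05, raw p-values (no multiple-testing
correction), no sample exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decompose import PARAMETER_NAMES, ParameterMaps

__all__ = [
    "GROUPS",
    "COMPARISONS",
    "SampleSummary",
    "ComparisonResult",
    "summarize_sample",
    "normality_gate",
    "compare_groups",
    "run_comparisons",
    "results_to_frame",
]

GROUPS = ("healthy", "cEDS", "hEDS")

#: comparison name -> (group-A selector, group-B selector)
COMPARISONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "EDS-vs-healthy": (("cEDS", "hEDS"), ("healthy",)),
    "cEDS-vs-hEDS": (("cEDS",), ("hEDS",)),
}


@dataclass
class SampleSummary:
    """Per-sample descriptors (median/mean/std per parameter) over masked pixels."""

    sample_id: str
    group: str
    median: dict[str, float]
    mean: dict[str, float]
    std: dict[str, float]
    n_pixels: int


@dataclass
class ComparisonResult:
    """One statistical test: a parameter under one group comparison."""

    parameter: str
    comparison: str
    test_used: str  # "t-test" | "mann-whitney"
    normality_p_A: float
    normality_p_B: float
    statistic: float
    p_value: float
    significant: bool
    n_A: int = 0
    n_B: int = 0


def summarize_sample(
    maps: ParameterMaps, mask, sample_id: str, group: str
) -> SampleSummary:
    """Reduce a sample's parameter maps to median/mean/std over masked, finite pixels."""
    from .acquisition import TissueMask

    mask_arr = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask: cannot summarize sample")
    med, mean, std = {}, {}, {}
    n_pixels = 0
    for name in PARAMETER_NAMES:
        vals = maps[name][mask_arr]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no finite pixels for parameter {name!r}")
        med[name] = float(np.median(vals))
        mean[name] = float(np.mean(vals))
        std[name] = float(np.std(vals))
        n_pixels = max(n_pixels, vals.size)
    return SampleSummary(sample_id, group, med, mean, std, n_pixels)


def normality_gate(values_A, values_B, alpha_norm: float = 0.05) -> tuple[str, float, float]:
    """Choose the test: Shapiro-Wilk per group, t-test only if both pass.

    Returns ``(test_name, p_A, p_B)``.  Constant groups cannot be tested for
    normality and fall through to Mann-Whitney (p reported as 0).
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values per group")
    ps = []
    for v in (a, b):
        if np.ptp(v) == 0:
            ps.append(0.0)
            continue
        # A numerically degenerate spread (e.g. floating-point dust around a
        # structurally zero parameter) cannot be assessed for normality;
        # treat it as failing the gate rather than trusting the fault.
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*range zero.*")
            try:
                ps.append(float(sps.shapiro(v).pvalue))
            except UserWarning:
                ps.append(0.0)
    test = "t-test" if (ps[0] > alpha_norm and ps[1] > alpha_norm) else "mann-whitney"
    return test, ps[0], ps[1]


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null when both n <= 12 and no ties,
    otherwise the tie- and continuity-corrected normal approximation."""
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and a.size <= 12 and b.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values_A,
    values_B,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    welch: bool = True,
    parameter: str = "",
    comparison: str = "",
) -> ComparisonResult:
    """Gated two-tailed comparison of two groups of per-sample medians."""
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 samples")
    # Degenerate-variance guard: identical constant groups differ in nothing.
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return ComparisonResult(
            parameter, comparison, "degenerate", 0.0, 0.0,
            statistic=0.0, p_value=1.0, significant=False, n_A=a.size, n_B=b.size,
        )
    test, p_A, p_B = normality_gate(a, b, alpha_norm=alpha_norm)
    if test == "t-test":
        res = sps.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = _mann_whitney(a, b)
    return ComparisonResult(
        parameter, comparison, test, p_A, p_B,
        statistic=stat, p_value=p, significant=bool(p < alpha),
        n_A=a.size, n_B=b.size,
    )


def run_comparisons(
    summaries: list[SampleSummary], alpha: float = 0.05, alpha_norm: float = 0.05,
    welch: bool = True,
) -> list[ComparisonResult]:
    """Run both group comparisons for every parameter (48 tests).

    Pooled-EDS merges the cEDS and hEDS per-sample medians.  Results are
    ordered by comparison, then by the parameter catalogue order.
    """
    by_group: dict[str, list[SampleSummary]] = {g: [] for g in GROUPS}
    for s in summaries:
        if s.group not in by_group:
            raise ValueError(f"unknown group label {s.group!r}")
        by_group[s.group].append(s)
    for g in GROUPS:
        if len(by_group[g]) == 0:
            raise ValueError(f"missing group: {g!r}")
    results = []
    for comparison, (sel_A, sel_B) in COMPARISONS.items():
        pool_A = [s for g in sel_A for s in by_group[g]]
        pool_B = [s for g in sel_B for s in by_group[g]]
        for name in PARAMETER_NAMES:
            a = [s.median[name] for s in pool_A]
            b = [s.median[name] for s in pool_B]
            results.append(
                compare_groups(
                    a, b, alpha=alpha, alpha_norm=alpha_norm, welch=welch,
                    parameter=name, comparison=comparison,
                )
            )
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results, one row per parameter x comparison."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "parameter": [r.parameter for r in results],
            "test_used": [r.test_used for r in results],
            "normality_p_A": [r.normality_p_A for r in results],
            "normality_p_B": [r.normality_p_B for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "n_A": [r.n_A for r in results],
            "n_B": [r.n_B for r in results],
        }
    )
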