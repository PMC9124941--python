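"""Cohort-level statistics over a fragility-annotated trial corpus.

Descriptives are medians with interquartile ranges (linear interpolation
between order statistics, the h = (n-1)p + 1 convention).  Subgroup contrasts
of the fragility index use the Mann-Whitney U test for two groups and the
Kruskal-Wallis test for three or more; correlations with trial
characteristics use Spearman's rank correlation.  No multiplicity adjustment
is applied — each characteristic is reported with its raw p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import JOURNAL_GROUPS, YEAR_BINS

__all__ = [
    "CohortSummary",
    "GroupStat",
    "SubgroupComparison",
    "CorrelationResult",
    "median_iqr",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman",
    "summarize_cohort",
    "build_table1",
    "correlate_fi",
]

logger = logging.getLogger("fragix")

#: Quartiles from fewer than this many observations are reported as
#: not-available (singleton and near-singleton subgroups).
MIN_N_FOR_IQR = 4


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr requires a non-empty collection")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def mann_whitney_u(x, y, continuity: bool = True) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from joint mid-ranks.  The p-value uses exact enumeration
    when neither sample exceeds 8 observations and there are no ties, and the
    tie-corrected normal approximation (with a 0.5 continuity correction
    unless ``continuity=False``) otherwise.  Returns ``(U, p)`` where U is the
    statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "auto" if continuity else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H test across three or more groups.

    H is computed from joint mid-ranks with tie correction; the p-value is
    the chi-square upper tail on k-1 degrees of freedom.  When every value in
    every group is identical the statistic is defined as 0 with p = 1.
    Two-group contrasts belong to :func:`mann_whitney_u`.
    """
    if len(groups) < 3:
        raise ValueError("kruskal_wallis requires >= 3 groups; use mann_whitney_u")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between the FI and one trial characteristic."""

    x_name: str
    y_name: str
    rho: float
    p_value: float
    n_pairs: int


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman's rank correlation (Pearson correlation of mid-ranks), with a
    p-value from the t approximation on n-2 degrees of freedom.  Pairs with a
    missing value in either variable are dropped pairwise; at least three
    complete pairs are required."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"spearman requires >= 3 complete pairs, got {n}")
    dropped = x.size - n
    if dropped:
        logger.info("spearman(%s, %s): dropped %d incomplete pair(s)", x_name, y_name, dropped)
    res = stats.spearmanr(x[mask], y[mask])
    return CorrelationResult(x_name, y_name, float(res.statistic), float(res.pvalue), n)


@dataclass(frozen=True)
class GroupStat:
    """One subgroup level: count, share, and median FI with IQR (IQR omitted
    for groups smaller than :data:`MIN_N_FOR_IQR`)."""

    label: str
    n: int
    pct: float
    median: Optional[float]
    iqr: Optional[tuple[float, float]]


@dataclass(frozen=True)
class SubgroupComparison:
    """A characteristic's subgroup contrast of the fragility index."""

    variable: str
    groups: list[GroupStat]
    test: Optional[str]
    statistic: Optional[float]
    p_value: Optional[float]


@dataclass(frozen=True)
class CohortSummary:
    """Headline descriptives of a fragility-annotated cohort."""

    n_trials: int
    median_fi: float
    iqr_fi: tuple[float, float]
    median_fq: float
    iqr_fq: tuple[float, float]
    median_n: float
    iqr_n: tuple[float, float]
    fi_histogram: dict[int, int]
    n_fi_le3: int
    n_fi_eq1: int
    n_nplfu_gt_fi: int
    n_exhausted_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "median_fi": self.median_fi,
            "iqr_fi": list(self.iqr_fi),
            "median_fq": self.median_fq,
            "iqr_fq": list(self.iqr_fq),
            "median_n": self.median_n,
            "iqr_n": list(self.iqr_n),
            "fi_histogram": {str(k): v for k, v in self.fi_histogram.items()},
            "n_fi_le3": self.n_fi_le3,
            "n_fi_eq1": self.n_fi_eq1,
            "n_nplfu_gt_fi": self.n_nplfu_gt_fi,
            "n_exhausted_excluded": self.n_exhausted_excluded,
        }


def _usable(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop exhausted rows (no meaningful FI) with a logged count."""
    n_excl = int(df["exhausted"].sum())
    if n_excl:
        logger.warning("excluding %d exhausted trial(s) from cohort statistics", n_excl)
    return df.loc[~df["exhausted"]], n_excl


def summarize_cohort(df: pd.DataFrame) -> CohortSummary:
    """Headline descriptives of an :func:`~fragix.corpus.attach_fragility`
    table: median (IQR) of FI, FQ and sample size, the FI histogram, and the
    counts of fragile trials (FI <= 3, FI = 1) and of trials whose loss to
    follow-up exceeds their FI."""
    df, n_excl = _usable(df)
    if len(df) == 0:
        raise ValueError("no usable trials in the cohort")
    med_fi, q1_fi, q3_fi = median_iqr(df["fi"])
    med_fq, q1_fq, q3_fq = median_iqr(df["fq"])
    med_n, q1_n, q3_n = median_iqr(df["n_total"])
    hist = df["fi"].value_counts().sort_index()
    return CohortSummary(
        n_trials=len(df),
        median_fi=med_fi,
        iqr_fi=(q1_fi, q3_fi),
        median_fq=med_fq,
        iqr_fq=(q1_fq, q3_fq),
        median_n=med_n,
        iqr_n=(q1_n, q3_n),
        fi_histogram={int(k): int(v) for k, v in hist.items()},
        n_fi_le3=int((df["fi"] <= 3).sum()),
        n_fi_eq1=int((df["fi"] == 1).sum()),
        n_nplfu_gt_fi=int(df["nplfu_exceeds_fi"].sum()),
        n_exhausted_excluded=n_excl,
    )


def _compare(df: pd.DataFrame, variable: str, labels: pd.Series,
             levels: Sequence[str]) -> SubgroupComparison:
    n_all = len(df)
    groups: list[GroupStat] = []
    fi_groups: list[np.ndarray] = []
    for level in levels:
        fi = df.loc[labels == level, "fi"].to_numpy(dtype=float)
        if fi.size == 0:
            groups.append(GroupStat(level, 0, 0.0, None, None))
            continue
        med, q1, q3 = median_iqr(fi)
        iqr = (q1, q3) if fi.size >= MIN_N_FOR_IQR else None
        groups.append(GroupStat(level, int(fi.size), 100.0 * fi.size / n_all, med, iqr))
        fi_groups.append(fi)
    if len(fi_groups) >= 3:
        stat, p = kruskal_wallis(fi_groups)
        test = "kruskal_wallis"
    elif len(fi_groups) == 2:
        stat, p = mann_whitney_u(fi_groups[0], fi_groups[1])
        test = "mann_whitney_u"
    else:
        test, stat, p = None, None, None
    return SubgroupComparison(variable, groups, test, stat, p)


def _binary_labels(series: pd.Series) -> pd.Series:
    """Collapse yes/no/unsure to the report's yes vs no-or-unsure split."""
    return series.map(lambda v: "yes" if v == "yes" else "no_or_unsure")


def build_table1(df: pd.DataFrame) -> list[SubgroupComparison]:
    """Subgroup contrasts of the FI for each trial characteristic, in report
    order: NPLFU vs FI, publication-year bin, multicenter, double-blinded,
    registration, intention-to-treat, outcome used, journal group.  Tri-state
    design flags are pooled to yes vs no-or-unsure.  Requires an
    :func:`~fragix.corpus.attach_fragility` table; exhausted trials are
    excluded first."""
    df, _ = _usable(df)
    if len(df) == 0:
        raise ValueError("no usable trials in the cohort")
    out = [
        _compare(
            df, "nplfu_vs_fi",
            df["nplfu_exceeds_fi"].map({True: "nplfu_gt_fi", False: "nplfu_le_fi"}),
            ["nplfu_gt_fi", "nplfu_le_fi"],
        ),
        _compare(df, "year_bin", df["year_bin"], list(YEAR_BINS)),
        _compare(df, "multicenter", _binary_labels(df["multicenter"]), ["yes", "no_or_unsure"]),
        _compare(df, "double_blinded", _binary_labels(df["double_blinded"]), ["yes", "no_or_unsure"]),
        _compare(df, "registered", _binary_labels(df["registered"]), ["yes", "no_or_unsure"]),
        _compare(df, "itt", df["itt"].map({True: "yes", False: "no"}), ["yes", "no"]),
        _compare(df, "outcome_used", df["outcome_used"], ["primary", "secondary"]),
        _compare(df, "journal_group", df["journal_group"], list(JOURNAL_GROUPS)),
    ]
    return out


def correlate_fi(df: pd.DataFrame) -> list[CorrelationResult]:
    """Spearman correlations of the FI with total sample size, total number
    of events, and the trial-reported p-value.  Pairs lacking a reported p
    are dropped pairwise (logged); a panel with fewer than three usable pairs
    is omitted with a warning."""
    df, _ = _usable(df)
    panels = [
        ("fi", "n_total"),
        ("fi", "total_events"),
        ("fi", "reported_p"),
    ]
    results = []
    for x_name, y_name in panels:
        try:
            results.append(
                spearman(df[x_name], df[y_name], x_name=x_name, y_name=y_name)
            )
        except ValueError as exc:
            logger.warning("omitting correlation panel (%s, %s): %s", x_name, y_name, exc)
    return results
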