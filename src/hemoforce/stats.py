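"""Cohort statistics with distribution-gated test selection.

Small pediatric imaging cohorts rarely justify parametric assumptions, so
every continuous variable is first gated by Shapiro-Wilk: normal on the raw
scale -> t-tests and Pearson correlation; normal only after log transform
(all-positive variables) -> the same tests on the log scale; otherwise ->
Mann-Whitney U / Wilcoxon signed-rank and Spearman correlation.  Categorical
contrasts use the chi-square test without continuity correction.  Summaries
are median [interquartile range].  No multiple-testing correction is
applied; this is an exploratory-analysis workflow with significance at
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateDataError

__all__ = [
    "StatResult",
    "assess_distribution",
    "compare_groups",
    "correlate",
    "categorical_test",
    "summarize",
    "compare_cohort",
    "ALPHA",
    "SHAPIRO_GATE_P",
]

#: Significance level used throughout.
ALPHA = 0.05
#: Shapiro-Wilk p-value at or above which a scale is accepted as normal.
SHAPIRO_GATE_P = 0.05
#: Largest sample size for which the exact signed-rank null is enumerated;
#: the normal approximation takes over above it.
EXACT_SIGNRANK_MAX_N = 12


@dataclass
class StatResult:
    """Outcome of one statistical comparison or association."""

    variable: str
    comparison: str  # control-vs-pre | pre-vs-post | control-vs-post | association
    test_name: str
    statistic: float
    p_value: float
    estimate: Optional[float] = None
    scale_used: str = "raw"
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _as_array(values) -> np.ndarray:
    arr = np.asarray(values, float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DataError("values must be finite")
    return arr


def assess_distribution(values) -> str:
    """Classify a sample as ``normal``, ``lognormal`` or ``nonnormal``.

    Normal if Shapiro-Wilk p >= 0.05 on the raw scale; else lognormal if all
    values are positive and Shapiro-Wilk passes on the log scale; else
    nonnormal.
    """
    arr = _as_array(values)
    if arr.size < 3:
        raise DataError(f"normality assessment needs n >= 3, got n = {arr.size}")
    if np.ptp(arr) == 0:
        return "nonnormal"  # Shapiro-Wilk is undefined for a constant sample
    if sps.shapiro(arr).pvalue >= SHAPIRO_GATE_P:
        return "normal"
    if np.all(arr > 0) and sps.shapiro(np.log(arr)).pvalue >= SHAPIRO_GATE_P:
        return "lognormal"
    return "nonnormal"


def compare_groups(
    x,
    y,
    paired: bool,
    distribution: Optional[str] = None,
    variable: str = "",
    comparison: str = "",
) -> StatResult:
    """Two-sample comparison routed by distributional class.

    normal -> Student's t-test (paired or unpaired); lognormal -> the same
    t-test on log-transformed values; nonnormal -> Wilcoxon signed-rank
    (paired; exact null for n <= 12) or Mann-Whitney U (unpaired).  Two-sided
    p-values throughout.
    """
    x, y = _as_array(x), _as_array(y)
    if paired and x.size != y.size:
        raise DataError(f"paired samples must have equal length ({x.size} vs {y.size})")
    if distribution is None:
        distribution = assess_distribution(np.concatenate([x, y]))
    scale = "raw"
    if distribution == "lognormal":
        if np.any(x <= 0) or np.any(y <= 0):
            raise DataError("log transform requires strictly positive values")
        x, y = np.log(x), np.log(y)
        scale = "log"

    if distribution in ("normal", "lognormal"):
        if paired:
            d = x - y
            if np.ptp(d) == 0 and d[0] == 0:
                raise DegenerateDataError("paired differences are identically zero")
            if np.ptp(d) == 0:
                raise DegenerateDataError("paired differences have zero variance")
            res = sps.ttest_rel(x, y)
            name = "paired t-test"
            est = float(np.mean(d))
        else:
            res = sps.ttest_ind(x, y)
            name = "unpaired t-test"
            est = float(np.mean(x) - np.mean(y))
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            d = x - y
            if np.all(d == 0):
                raise DegenerateDataError("no nonzero paired differences to rank")
            n_nonzero = int(np.count_nonzero(d))
            method = "exact" if n_nonzero <= EXACT_SIGNRANK_MAX_N else "approx"
            try:
                res = sps.wilcoxon(x, y, method=method)
            except ValueError:
                res = sps.wilcoxon(x, y, method="approx")
            name = "Wilcoxon signed-rank"
            est = float(np.median(d))
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            name = "Mann-Whitney U"
            est = float(np.median(x) - np.median(y))
        stat, p = float(res.statistic), float(res.pvalue)

    return StatResult(
        variable=variable,
        comparison=comparison or ("pre-vs-post" if paired else "control-vs-pre"),
        test_name=name,
        statistic=stat,
        p_value=min(p, 1.0),
        estimate=est,
        scale_used=scale,
        n=int(x.size),
    )


def correlate(
    x, y, distribution: Optional[str] = None, variable: str = ""
) -> StatResult:
    """Association between two variables: Pearson (raw or log scale) for
    normal / lognormal data, Spearman rank correlation otherwise."""
    x, y = _as_array(x), _as_array(y)
    if x.size != y.size:
        raise DataError("correlation requires equal-length vectors")
    if x.size < 3:
        raise DataError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    if distribution is None:
        distribution = assess_distribution(x)
    scale = "raw"
    if distribution == "lognormal":
        if np.any(x <= 0) or np.any(y <= 0):
            distribution = "nonnormal"
        else:
            x, y = np.log(x), np.log(y)
            scale = "log"
    if distribution in ("normal", "lognormal"):
        res = sps.pearsonr(x, y)
        name = "Pearson correlation"
    else:
        res = sps.spearmanr(x, y)
        name = "Spearman correlation"
    r = float(res.statistic)
    return StatResult(
        variable=variable,
        comparison="association",
        test_name=name,
        statistic=r,
        p_value=float(res.pvalue),
        estimate=r,
        scale_used=scale,
        n=int(x.size),
    )


def categorical_test(table_2xk, variable: str = "", comparison: str = "") -> StatResult:
    """Chi-square test of independence on a 2 x k count table, no continuity
    correction."""
    table = np.asarray(table_2xk, float)
    if table.ndim != 2 or np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise DataError("expected a 2D table of nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("a zero marginal makes the chi-square test undefined")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(
        variable=variable,
        comparison=comparison or "control-vs-pre",
        test_name="chi-square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=None,
        n=int(table.sum()),
    )


def summarize(values) -> dict:
    """Median [IQR] summary: median, 25th and 75th percentiles plus a
    formatted display string."""
    arr = _as_array(values)
    if arr.size == 0:
        raise DataError("cannot summarize an empty sample")
    med = float(np.median(arr))
    q25, q75 = (float(q) for q in np.percentile(arr, [25, 75]))
    return {
        "median": med,
        "q25": q25,
        "q75": q75,
        "display": f"{med:g} [{q25:g}–{q75:g}]",
    }


def compare_cohort(
    table: pd.DataFrame,
    variables: Sequence[str],
    id_col: str = "id",
    group_col: str = "group",
    visit_col: str = "visit",
) -> pd.DataFrame:
    """Run the full comparison layout on a cohort table.

    For each variable: control vs patient-baseline (unpaired), patient
    baseline vs follow-up (paired on subject id), and control vs
    patient-follow-up (unpaired), each gated by its own distribution
    assessment.  Returns one row per variable x comparison.
    """
    controls = table[(table[group_col] == "control")]
    pre = table[(table[group_col] == "patient") & (table[visit_col] == "baseline")]
    post = table[(table[group_col] == "patient") & (table[visit_col] == "followup")]
    paired_ids = sorted(set(pre[id_col]) & set(post[id_col]))
    pre_p = pre.set_index(id_col).loc[paired_ids]
    post_p = post.set_index(id_col).loc[paired_ids]

    rows = []
    for var in variables:
        blocks = [
            ("control-vs-pre", controls[var].dropna(), pre[var].dropna(), False),
            ("pre-vs-post", pre_p[var], post_p[var], True),
            ("control-vs-post", controls[var].dropna(), post[var].dropna(), False),
        ]
        for comparison, a, b, paired in blocks:
            if paired:
                keep = a.notna() & b.notna()
                a, b = a[keep], b[keep]
            if len(a) < 3 or len(b) < 3:
                continue
            dist = assess_distribution(np.concatenate([a, b]))
            try:
                res = compare_groups(
                    a, b, paired=paired, distribution=dist,
                    variable=var, comparison=comparison,
                )
            except DegenerateDataError:
                continue
            rows.append(
                {
                    "variable": var,
                    "comparison": comparison,
                    "test": res.test_name,
                    "scale": res.scale_used,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "estimate": res.estimate,
                    "n": res.n,
                    "summary_a": summarize(a)["display"],
                    "summary_b": summarize(b)["display"],
                }
            )
    return pd.DataFrame(rows)
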