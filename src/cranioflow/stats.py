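"""Cohort statistics: outlier exclusion, normality-gated comparisons,
correlation with strength classification, and summary reporting.

The statistical layer mirrors common practice in small-cohort PC-MRI
studies: per-metric single-pass outlier exclusion against the interval
[mean − 1.5·IQR, mean + 1.5·IQR]; Shapiro-gated choice between
parametric (t) and nonparametric (Mann–Whitney / Wilcoxon) two-sided
tests; Pearson correlation with |r| strength bands.  No multiple-testing
correction is applied (each test is reported at p < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import SubjectMetrics

__all__ = [
    "exclude_outliers",
    "compare_groups",
    "correlate",
    "classify_correlation",
    "build_report",
    "ComparisonResult",
    "CorrelationResult",
    "CohortReport",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: |r| strength bands (half-open; exhaustive over [0, 1])
_CORRELATION_BANDS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.50, "moderate"),
    (0.30, "weak"),
    (0.00, "below-weak"),
)

#: (extracranial, intracranial) metric pairs compared within-group
PAIRED_METRICS = (
    ("extra_acbf", "intra_acbf"),
    ("extra_vcbf", "intra_vcbf"),
    ("alpha_extra", "alpha_intra"),
    ("extra_blood_sv", "intra_blood_sv"),
    ("extra_arterial_pi", "intra_arterial_pi"),
    ("extra_venous_pi", "intra_venous_pi"),
)

#: correlation panel: (x, y) metric pairs examined per group
CORRELATION_PAIRS = (
    ("aqueductal_csf_sv", "spinal_csf_sv"),
    ("spinal_csf_sv", "extra_blood_sv"),
    ("spinal_csf_sv", "intra_blood_sv"),
)


def exclude_outliers(
    values: Sequence[float], use_median: bool = False
) -> Tuple[np.ndarray, List[int]]:
    """Single-pass outlier exclusion against mean ± 1.5·IQR.

    Values strictly outside [center − 1.5·IQR, center + 1.5·IQR] are
    excluded, where the center is the sample mean (``use_median=True``
    switches to the Tukey median-based variant) and IQR = Q3 − Q1 with
    linearly interpolated quartiles.  NaNs are ignored (kept out of both
    the bounds and the output).  Returns (kept values, excluded indices).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values for outlier screening")
    vf = v[finite]
    q1, q3 = np.percentile(vf, [25, 75])  # linear interpolation
    iqr = q3 - q1
    if iqr == 0 and np.ptp(vf) > 0:
        logger.warning("IQR is zero with spread values; excluding nothing")
        return vf, []
    center = float(np.median(vf) if use_median else vf.mean())
    lo, hi = center - 1.5 * iqr, center + 1.5 * iqr
    excluded = [int(i) for i in np.flatnonzero(finite & ((v < lo) | (v > hi)))]
    kept = v[finite & (v >= lo) & (v <= hi)]
    return kept, excluded


@dataclass
class ComparisonResult:
    """Outcome of one two-sample comparison."""

    parameter: str
    design: str  # "independent" or "paired"
    test: str  # "t", "mann-whitney", or "wilcoxon"
    statistic: float
    p_value: float
    n: Tuple[int, int]

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    @property
    def stars(self) -> str:
        p = self.p_value
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def _is_normal(x: np.ndarray) -> bool:
    """Shapiro–Wilk at 0.05; degenerate (constant) samples count as
    non-normal so they fall through to rank tests."""
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > ALPHA


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    design: str = "independent",
    parameter: str = "",
) -> ComparisonResult:
    """Two-sided two-sample comparison with a Shapiro normality gate.

    Both samples normal → Student t (paired or independent); otherwise
    Wilcoxon signed-rank (paired) or Mann–Whitney U (independent).
    NaNs are dropped (pairwise for the paired design).
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design == "paired":
        if len(x) != len(y):
            raise ValueError("paired design requires equal-length samples")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    else:
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    if design == "paired" and np.all(x == y):
        # zero effect everywhere: degenerate for both t and signed-rank
        return ComparisonResult(parameter, design, "wilcoxon", 0.0, 1.0,
                                (len(x), len(y)))

    normal = _is_normal(x) and _is_normal(y)
    if design == "independent":
        if normal:
            res = sps.ttest_ind(x, y)
            test = "t"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            test = "mann-whitney"
    else:
        if normal:
            res = sps.ttest_rel(x, y)
            test = "t"
        else:
            res = sps.wilcoxon(x, y)
            test = "wilcoxon"
    return ComparisonResult(parameter, design, test, float(res.statistic),
                            float(res.pvalue), (len(x), len(y)))


def classify_correlation(r: float) -> str:
    """Strength class of a correlation coefficient from |r| bands:
    [0.30, 0.50) weak, [0.50, 0.70) moderate, [0.70, 0.90) strong,
    >= 0.90 very strong, < 0.30 below-weak."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    a = abs(r)
    for cut, name in _CORRELATION_BANDS:
        if a >= cut:
            return name
    return "below-weak"


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p_value: float
    strength: str
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation between two cohort metrics.

    Rows with a missing value in either metric are dropped pairwise;
    at least 4 complete pairs are required.
    """
    xv = pd.to_numeric(table[x], errors="coerce")
    yv = pd.to_numeric(table[y], errors="coerce")
    keep = xv.notna() & yv.notna()
    xv, yv = xv[keep].to_numpy(), yv[keep].to_numpy()
    if len(xv) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(x, y, float(r), float(p), classify_correlation(float(r)), len(xv))


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class CohortReport:
    """Summary of a two-group cohort analysis."""

    summary: pd.DataFrame  # per-parameter descriptives + between-group tests
    paired: pd.DataFrame  # within-group extracranial-vs-intracranial tests
    correlations: pd.DataFrame  # correlation panel per group
    ratios: pd.DataFrame  # derived percentage ratios from group means
    exclusions: pd.DataFrame  # outlier log: group, metric, subject, value, bounds

    def to_markdown(self) -> str:
        parts = ["# Cohort flow report", ""]
        for title, df in (
            ("Per-parameter summary (mean ± SD (min–max); between-group test)", self.summary),
            ("Within-group extracranial vs intracranial (paired)", self.paired),
            ("Correlation panel", self.correlations),
            ("Derived ratios from group means", self.ratios),
            ("Outlier exclusions", self.exclusions),
        ):
            parts += [f"## {title}", "", df.to_string(index=False), ""]
        parts += ["No multiple-testing correction applied; each test reported at p < 0.05."]
        return "\n".join(parts)


def _descriptive(v: np.ndarray) -> str:
    return f"{np.mean(v):.3g} ± {np.std(v, ddof=1):.3g} ({np.min(v):.3g}–{np.max(v):.3g})"


def build_report(
    table: pd.DataFrame,
    exclude: bool = True,
    use_median: bool = False,
) -> CohortReport:
    """Build a two-group summary from a per-subject metrics table.

    ``table`` needs a ``group`` column (HYV / HEV, or any ≤2 labels) plus
    the :class:`~cranioflow.quantify.SubjectMetrics` columns.  Outlier
    exclusion (``exclude=True``) is applied per metric and per group
    before testing, matching per-metric screening rather than listwise
    subject deletion.  With a single group, between-group columns are
    marked not applicable.
    """
    if "group" not in table.columns:
        raise ValueError("table needs a 'group' column")
    groups = [g for g in table["group"].unique()]
    if not groups or any(len(table[table["group"] == g]) == 0 for g in groups):
        raise ValueError("empty group in cohort table")
    two_groups = len(groups) == 2

    metric_names = [m for m in SubjectMetrics.metric_names() if m in table.columns]
    excl_rows = []
    cleaned: Dict[Tuple[str, str], np.ndarray] = {}
    for g in groups:
        sub = table[table["group"] == g]
        for metric in metric_names:
            vals = pd.to_numeric(sub[metric], errors="coerce").to_numpy()
            finite = vals[np.isfinite(vals)]
            if exclude and len(finite) >= 4:
                kept, excluded = exclude_outliers(vals, use_median=use_median)
                for idx in excluded:
                    excl_rows.append({
                        "group": g, "metric": metric,
                        "subject_id": sub.iloc[idx].get("subject_id", str(sub.index[idx])),
                        "value": vals[idx],
                    })
                cleaned[(g, metric)] = kept
            else:
                cleaned[(g, metric)] = finite

    summary_rows = []
    for metric in metric_names:
        row: Dict[str, object] = {"parameter": metric}
        for g in groups:
            row[f"{g} mean±SD (min–max)"] = _descriptive(cleaned[(g, metric)]) \
                if len(cleaned[(g, metric)]) else "n/a"
        if two_groups and all(len(cleaned[(g, metric)]) >= 3 for g in groups):
            res = compare_groups(cleaned[(groups[0], metric)], cleaned[(groups[1], metric)],
                                 design="independent", parameter=metric)
            row["between p"] = res.p_value
            row["between test"] = res.test
            row["sig"] = res.stars
        else:
            row["between p"] = np.nan
            row["between test"] = "n/a"
            row["sig"] = "n/a"
        summary_rows.append(row)

    paired_rows = []
    for g in groups:
        sub = table[table["group"] == g]
        for extra_m, intra_m in PAIRED_METRICS:
            if extra_m not in table.columns or intra_m not in table.columns:
                continue
            x = pd.to_numeric(sub[extra_m], errors="coerce").to_numpy()
            y = pd.to_numeric(sub[intra_m], errors="coerce").to_numpy()
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                continue
            res = compare_groups(x[keep], y[keep], design="paired",
                                 parameter=f"{extra_m} vs {intra_m}")
            paired_rows.append({
                "group": g, "pair": res.parameter, "test": res.test,
                "p": res.p_value, "sig": res.stars,
            })

    corr_rows = []
    for g in groups:
        sub = table[table["group"] == g]
        for x, y in CORRELATION_PAIRS:
            if x not in table.columns or y not in table.columns:
                continue
            try:
                res = correlate(sub, x, y)
            except ValueError:
                continue
            corr_rows.append({
                "group": g, "x": x, "y": y, "r": res.r, "p": res.p_value,
                "strength": res.strength, "n": res.n,
            })

    ratio_rows = []
    for g in groups:
        means = {m: float(np.mean(cleaned[(g, m)])) if len(cleaned[(g, m)]) else np.nan
                 for m in metric_names}
        ratio_rows.append({
            "group": g,
            "aqueductal/spinal CSF SV (%)":
                100.0 * means.get("aqueductal_csf_sv", np.nan) / means.get("spinal_csf_sv", np.nan),
            "sinus drainage IntraVCBF/IntraACBF (%)":
                100.0 * means.get("intra_vcbf", np.nan) / means.get("intra_acbf", np.nan),
            "jugular drainage ExtraVCBF/ExtraACBF (%)":
                100.0 * means.get("extra_vcbf", np.nan) / means.get("extra_acbf", np.nan),
        })

    return CohortReport(
        summary=pd.DataFrame(summary_rows),
        paired=pd.DataFrame(paired_rows),
        correlations=pd.DataFrame(corr_rows),
        ratios=pd.DataFrame(ratio_rows),
        exclusions=pd.DataFrame(excl_rows, columns=["group", "metric", "subject_id", "value"]),
    )
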