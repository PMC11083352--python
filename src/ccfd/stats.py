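"""Longitudinal cohort statistics.

Normality is screened with the Shapiro–Wilk test (reported alongside, never
gating, the paired comparisons).  Visit contrasts (T1 vs T0, T2 vs T0,
T2 vs T1) use two-sided paired t-tests per ring and per metric with a
significance level of 0.05 and no multiple-testing correction; an optional
Bonferroni-adjusted flag column is provided as a clearly labelled extra.
Interobserver agreement uses the two-way random-effects, absolute-agreement,
average-measures intraclass correlation coefficient ICC(A,k) of
McGraw & Wong, with a 95% CI from the F-distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
import scipy.stats as sps

from .types import TIMEPOINTS, FDResult

__all__ = [
    "PairedTestResult",
    "shapiro_wilk",
    "paired_t_test",
    "icc_average",
    "results_to_cohort",
    "LongitudinalReport",
    "build_report",
]

METRICS = ("fd_percent", "fd_avg_area_um2", "fd_count")
CONTRASTS = (("T1", "T0"), ("T2", "T0"), ("T2", "T1"))


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test summary for one visit contrast."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    t_statistic: float
    df: int
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero-variance differences


def shapiro_wilk(sample: Iterable[float]) -> Tuple[float, float]:
    """Shapiro–Wilk normality test (Royston's AS R94 approximation).

    Requires 3 ≤ n ≤ 5000 and a non-constant sample.  Returns (W, p).
    """
    x = np.asarray(list(sample), dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk approximation is valid up to n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W is undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x: Iterable[float], y: Iterable[float]) -> PairedTestResult:
    """Two-sided paired t-test of visit A values ``x`` against visit B
    values ``y`` (pairs matched by position, i.e. by eye).

    d = x − y; t = mean(d) / (sd(d)/√n), df = n − 1.  A zero-variance
    difference vector is flagged degenerate: t = ±∞ with p = 0 when the
    mean difference is nonzero, t = 0 with p = 1 when all differences
    vanish.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p, degen = 0.0, 1.0, True
        else:
            t, p, degen = float(np.sign(mean_d) * np.inf), 0.0, True
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
        degen = False
    return PairedTestResult(
        mean_a=float(x.mean()),
        sd_a=float(x.std(ddof=1)),
        mean_b=float(y.mean()),
        sd_b=float(y.std(ddof=1)),
        mean_diff=mean_d,
        t_statistic=float(t),
        df=n - 1,
        p_value=p,
        n_pairs=n,
        degenerate=degen,
    )


def icc_average(
    measurements: np.ndarray, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """ICC(A,k): two-way random-effects, absolute-agreement, average-measures
    intraclass correlation (McGraw & Wong), with its (1−alpha) CI.

    Parameters
    ----------
    measurements : (n_targets, n_raters) array
        Complete matrix of ratings (e.g. per-eye MNV areas from each
        grader).

    Returns
    -------
    (icc, ci_low, ci_high)

    Notes
    -----
    The CI is obtained from the single-measures ICC(A,1) F-based bounds
    with Satterthwaite degrees of freedom, stepped up to average measures
    with the Spearman–Brown relation — the construction used by the
    standard reference implementations.
    """
    M = np.asarray(measurements, dtype=float)
    if M.ndim != 2:
        raise ValueError("measurements must be an (n_targets, n_raters) matrix")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(M)):
        raise ValueError("incomplete matrix: non-finite entries present")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((M - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom_k = msr + (msc - mse) / n
    if denom_k <= 0 or msr <= mse:
        warnings.warn(
            "degenerate agreement matrix (no between-target variance beyond "
            "error); ICC is not meaningful",
            RuntimeWarning,
        )
    icc_k = (msr - mse) / denom_k if denom_k != 0 else float("nan")

    # single-measures point estimate feeds the Satterthwaite df
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc_1 / (n * (1 - icc_1)) if icc_1 != 1 else np.inf
    b = 1 + k * icc_1 * (n - 1) / (n * (1 - icc_1)) if icc_1 != 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
        # Spearman-Brown step-up to average measures
        lo = lo1 * k / (1 + (k - 1) * lo1)
        hi = hi1 * k / (1 + (k - 1) * hi1)
    else:
        lo, hi = float("nan"), float("nan")
    return float(icc_k), float(lo), float(hi)


def results_to_cohort(results: Iterable[FDResult]) -> pd.DataFrame:
    """Flatten per-scan FD results into the long cohort table with one row
    per (eye, timepoint, ring, metric)."""
    rows: List[dict] = []
    for res in results:
        for rec in res.to_records():
            if not rec["defined"]:
                continue
            for metric in METRICS:
                rows.append(
                    {
                        "eye_id": rec["eye_id"],
                        "timepoint": rec["timepoint"],
                        "ring": rec["ring"],
                        "metric": metric,
                        "value": float(rec[metric]),
                    }
                )
    df = pd.DataFrame(rows, columns=["eye_id", "timepoint", "ring", "metric", "value"])
    dup = df.duplicated(["eye_id", "timepoint", "ring", "metric"])
    if dup.any():
        raise ValueError("duplicate (eye, timepoint, ring, metric) records")
    return df


@dataclass
class LongitudinalReport:
    """Mean ± SD per ring per visit with paired-test p-values, per metric.

    ``tests`` holds one row per (metric, ring, contrast) with the full
    paired-test summary; ``tables`` renders, per metric, the familiar
    5-ring × 3-visit mean ± SD layout with the p-values underneath.
    """

    tests: pd.DataFrame
    summary: pd.DataFrame
    alpha: float = 0.05

    @property
    def tables(self) -> Dict[str, pd.DataFrame]:
        out = {}
        for metric in self.summary["metric"].unique():
            sub = self.summary[self.summary["metric"] == metric]
            tab = sub.pivot(index="ring", columns="timepoint", values="mean_sd")
            out[metric] = tab
        return out

    def to_markdown(self) -> str:
        parts = []
        for metric, tab in self.tables.items():
            parts.append(f"### {metric}\n\n{tab.to_markdown()}\n")
        parts.append("### paired contrasts\n")
        cols = ["metric", "ring", "contrast", "mean_diff", "t_statistic", "p_value", "significant"]
        parts.append(self.tests[cols].to_markdown(index=False))
        return "\n".join(parts)


def build_report(
    cohort: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = True
) -> LongitudinalReport:
    """Assemble the longitudinal tables from a long cohort DataFrame with
    columns (eye_id, timepoint, ring, metric, value).

    For each metric and ring the mean ± SD is reported per visit, and
    paired t-tests compare T1 vs T0, T2 vs T0 and T2 vs T1 over the eyes
    present at both visits.  Cells with p < alpha are flagged significant;
    a Bonferroni-adjusted flag (alpha divided by the number of tests) is
    appended as an extra, clearly labelled column.

    Raises
    ------
    ValueError
        If fewer than 2 eyes have complete visit triples.
    """
    required = {"eye_id", "timepoint", "ring", "metric", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    complete = (
        cohort.groupby("eye_id")["timepoint"].nunique() >= len(TIMEPOINTS)
    )
    if int(complete.sum()) < 2:
        raise ValueError("insufficient pairs: need >= 2 eyes with complete visit triples")

    test_rows: List[dict] = []
    summary_rows: List[dict] = []
    for metric in cohort["metric"].unique():
        dm = cohort[cohort["metric"] == metric]
        for ring in sorted(dm["ring"].unique()):
            dr = dm[dm["ring"] == ring]
            wide = dr.pivot(index="eye_id", columns="timepoint", values="value")
            for tp in TIMEPOINTS:
                if tp not in wide.columns:
                    continue
                vals = wide[tp].dropna()
                summary_rows.append(
                    {
                        "metric": metric,
                        "ring": ring,
                        "timepoint": tp,
                        "n": int(vals.size),
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)),
                        "mean_sd": f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}",
                    }
                )
            for later, earlier in CONTRASTS:
                if later not in wide.columns or earlier not in wide.columns:
                    continue
                paired = wide[[later, earlier]].dropna()
                if len(paired) < 2:
                    continue
                res = paired_t_test(paired[later], paired[earlier])
                test_rows.append(
                    {
                        "metric": metric,
                        "ring": ring,
                        "contrast": f"{later}-vs-{earlier}",
                        "mean_a": res.mean_a,
                        "sd_a": res.sd_a,
                        "mean_b": res.mean_b,
                        "sd_b": res.sd_b,
                        "mean_diff": res.mean_diff,
                        "t_statistic": res.t_statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "n_pairs": res.n_pairs,
                        "significant": res.p_value < alpha,
                    }
                )
    tests = pd.DataFrame(test_rows)
    if bonferroni and not tests.empty:
        m = len(tests)
        tests["bonferroni_significant"] = tests["p_value"] < alpha / m
    summary = pd.DataFrame(summary_rows)
    return LongitudinalReport(tests=tests, summary=summary, alpha=alpha)
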