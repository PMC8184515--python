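"""Group-level statistics: Student's t, paired t, two-sample KS,
pre-treatment normalization.

Mirrors the study's analysis conventions: classical pooled-variance
Student's t for two-group comparisons (Welch available by flag), paired t
for pre/post drug epochs, two-sided two-sample Kolmogorov–Smirnov for
size/duration distributions, and per-fish normalization of drug-epoch
metrics to the mean of the untreated period.  No multiple-testing
correction is applied; reports carry the number of tests run so readers can
judge that themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "KSResult",
    "two_sample_t",
    "paired_t",
    "ks_two_sample",
    "normalize_to_pretreatment",
    "compare_groups",
]

GROUP_TABLE_COLUMNS = [
    "subject",
    "condition",
    "dpf",
    "n_cascades",
    "max_size",
    "max_duration_s",
    "n_ensembles",
    "avg_ensemble_size",
]


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    degenerate: bool = False


@dataclass
class KSResult:
    d: float
    p: float


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> TTestResult:
    """Two-sided two-sample t test; pooled variance (Student) by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    degenerate = False
    if not np.isfinite(t):  # both groups constant and equal
        t, p, degenerate = 0.0, 1.0, True
    return TTestResult(
        t=t,
        p=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        degenerate=degenerate,
    )


def paired_t(pre: np.ndarray, post: np.ndarray) -> TTestResult:
    """Two-sided paired t test (one-sample t on the differences)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = post - pre
    if np.ptp(d) == 0:  # zero-variance differences
        if d[0] == 0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if d[0] > 0 else -np.inf
            p = 0.0
        return TTestResult(
            t=float(t),
            p=float(p),
            mean_a=float(pre.mean()),
            sd_a=float(pre.std(ddof=1)),
            mean_b=float(post.mean()),
            sd_b=float(post.std(ddof=1)),
            degenerate=True,
        )
    res = stats.ttest_rel(pre, post)
    return TTestResult(
        t=float(-res.statistic),  # report in post-minus-pre orientation
        p=float(res.pvalue),
        mean_a=float(pre.mean()),
        sd_a=float(pre.std(ddof=1)),
        mean_b=float(post.mean()),
        sd_b=float(post.std(ddof=1)),
    )


def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> KSResult:
    """Two-sided two-sample KS test; exact p below combined n = 25."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if a.size + b.size < 25:
        res = stats.ks_2samp(a, b, method="exact")
        return KSResult(d=float(res.statistic), p=float(res.pvalue))
    # classical Kolmogorov (Smirnov limiting) asymptotic for larger samples
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(stats.kstwobign.sf(en * d))
    return KSResult(d=d, p=min(max(p, 0.0), 1.0))


def normalize_to_pretreatment(
    table: pd.DataFrame,
    metrics: list[str],
    fish_col: str = "fish",
    phase_col: str = "phase",
    pre_label: str = "pre",
    log=None,
) -> pd.DataFrame:
    """Divide each fish's metrics by that fish's mean pre-treatment value.

    Pre-treatment epochs therefore normalize to mean 1 per fish.  Fish whose
    pre-treatment mean of a metric is 0 get NaN for that metric (flagged and
    logged) so they drop out of downstream comparisons.
    """
    out = table.copy()
    for metric in metrics:
        norm = np.full(len(table), np.nan)
        for fish, grp in table.groupby(fish_col):
            pre_vals = grp.loc[grp[phase_col] == pre_label, metric]
            if pre_vals.empty:
                raise ValueError(f"fish {fish!r} has no pre-treatment epochs")
            denom = pre_vals.mean()
            if denom == 0 or not np.isfinite(denom):
                if log is not None:
                    log.exclude(
                        "normalize_to_pretreatment",
                        f"fish {fish!r}: pre-treatment mean of {metric!r} is 0",
                    )
                continue
            norm[grp.index.to_numpy()] = table.loc[grp.index, metric] / denom
        out[f"{metric}_norm"] = norm
    return out


def compare_groups(
    table: pd.DataFrame,
    group_col: str,
    metrics: list[str],
    tests: tuple[str, ...] = ("t", "ks"),
    subject_col: str | None = "subject",
    average_epochs: bool = True,
) -> dict:
    """Compare two conditions metric-by-metric.

    When ``average_epochs`` is set and a subject column exists, multiple
    epochs per subject are averaged first, so the experimental unit is the
    fish rather than the recording.
    """
    labels = sorted(table[group_col].dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, found {labels}")
    work = table
    if average_epochs and subject_col is not None and subject_col in table.columns:
        work = (
            table.groupby([group_col, subject_col], as_index=False)[metrics].mean()
        )
    report: dict = {"groups": [str(l) for l in labels], "metrics": {}, "n_tests": 0}
    for metric in metrics:
        a = work.loc[work[group_col] == labels[0], metric].to_numpy(dtype=float)
        b = work.loc[work[group_col] == labels[1], metric].to_numpy(dtype=float)
        entry: dict = {
            "n_a": int(a.size),
            "n_b": int(b.size),
        }
        if "t" in tests:
            r = two_sample_t(a, b)
            entry["t"] = {
                "t": r.t,
                "p": r.p,
                "mean_sd_a": [r.mean_a, r.sd_a],
                "mean_sd_b": [r.mean_b, r.sd_b],
            }
            report["n_tests"] += 1
        if "ks" in tests:
            r = ks_two_sample(a, b)
            entry["ks"] = {"d": r.d, "p": r.p}
            report["n_tests"] += 1
        report["metrics"][metric] = entry
    return report
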