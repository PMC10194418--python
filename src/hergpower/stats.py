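"""Group summaries and comparisons for repolarization-power cohorts.

Cohorts in this workflow are small (6–9 cells per condition), so the default
comparison is a non-parametric rank test: Wilcoxon signed-rank for paired
groups, Mann–Whitney U otherwise, with t-tests available on request.
Significance stars follow the usual two-threshold convention
(ns: p ≥ 0.05, *: p < 0.05, **: p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "compare", "stars_from_p", "tukey_plot"]

ALPHA_STAR = 0.05
ALPHA_DOUBLE_STAR = 0.01


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM plus Tukey box-plot statistics for one group."""

    label: str
    n: int
    mean: float
    sem: float
    quartiles: tuple  # (q1, median, q3)
    whiskers: tuple  # (low, high): most extreme data within 1.5×IQR fences
    outliers: tuple = ()


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    p_value: float
    stars: str  # "ns", "*", "**"
    test_name: str
    paired: bool


def stars_from_p(p_value: float) -> str:
    """Map a p-value onto the printed star convention."""
    if p_value < ALPHA_DOUBLE_STAR:
        return "**"
    if p_value < ALPHA_STAR:
        return "*"
    return "ns"


def summarize(values, label: str = "") -> GroupSummary:
    """Mean, SEM (sd/√n, ddof=1) and Tukey quartiles/whiskers for one group."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whiskers = (float(inside.min()), float(inside.max()))
    outliers = tuple(float(v) for v in np.sort(x[(x < lo_fence) | (x > hi_fence)]))
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return GroupSummary(
        label=label,
        n=int(x.size),
        mean=float(np.mean(x)),
        sem=sem,
        quartiles=(float(q1), float(med), float(q3)),
        whiskers=whiskers,
        outliers=outliers,
    )


_TESTS = ("wilcoxon", "mannwhitney", "ttest", "paired-ttest")


def compare(
    group_a,
    group_b,
    paired: bool = False,
    test: str | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Two-group comparison with star assignment.

    ``test`` defaults to "wilcoxon" (signed-rank) when paired and
    "mannwhitney" otherwise; "ttest"/"paired-ttest" switch to parametric
    tests.  Requires n ≥ 3 per group, equal n when paired.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal group sizes")
    if test is None:
        test = "wilcoxon" if paired else "mannwhitney"
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose one of {_TESTS}")

    if test == "wilcoxon":
        if not paired:
            raise ValueError("wilcoxon signed-rank requires paired=True")
        # zsplit keeps zero differences instead of erroring on identical groups
        p = float(sps.wilcoxon(a, b, zero_method="zsplit").pvalue)
    elif test == "mannwhitney":
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    elif test == "paired-ttest":
        if not paired:
            raise ValueError("paired-ttest requires paired=True")
        r = sps.ttest_rel(a, b)
        p = 1.0 if np.isnan(r.pvalue) else float(r.pvalue)
    else:
        p = float(sps.ttest_ind(a, b).pvalue)
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        p_value=p,
        stars=stars_from_p(p),
        test_name=test,
        paired=paired,
    )


def tukey_plot(groups: dict, path: str, ylabel: str = "repolarization power (pA·s)"):
    """Write a Tukey box plot (1.5×IQR whiskers) with mean±SEM overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(groups)
    data = [np.asarray(list(groups[k]), dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    for k, x in enumerate(data, start=1):
        s = summarize(x)
        ax.errorbar([k], [s.mean], yerr=[s.sem], fmt="D", color="crimson", capsize=4)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
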