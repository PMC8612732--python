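"""Group statistics and reporting: median / mean ± SEM summaries, two- and
multi-group tests (Student's t, one-way ANOVA + Tukey HSD, Šidák-adjusted
planned comparisons), fold-change / percent-increase arithmetic with the
display rounding used in figure legends, and robust outlier flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "ComparisonResult", "summarize_group", "fold_change",
           "compare_groups", "flag_outliers", "significance_stars", "sidak_adjust"]


@dataclass
class GroupSummary:
    label: str
    n: int
    median: float
    mean: float
    sem: float | None
    values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass
class ComparisonResult:
    test: str                      # "t" | "anova+tukey" | "anova+sidak"
    statistic: float               # t or F
    p: float                       # omnibus / two-group p
    pairs: pd.DataFrame            # per-pair raw and adjusted p-values


def summarize_group(values, label: str = "") -> GroupSummary:
    """Median, mean and SEM of one group; SEM is missing (None) for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return GroupSummary(label=label, n=int(v.size), median=float(np.median(v)),
                        mean=float(v.mean()), sem=sem, values=v)


def fold_change(mean_ref: float, mean_test: float) -> dict[str, float]:
    """Ratio and percent increase of a test mean over a reference mean.

    ``display_fold`` and ``display_percent`` apply the rounding used when
    such values are quoted (fold to 1 decimal, percent to integer).
    """
    if not np.isfinite(mean_ref) or mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    ratio = mean_test / mean_ref
    percent = 100.0 * (ratio - 1.0)
    return {
        "ratio": ratio,
        "percent_increase": percent,
        "display_fold": round(ratio, 1),
        "display_percent": round(percent),
    }


def significance_stars(p: float) -> str:
    """Asterisk convention: * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "ns"


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Šidák correction for m comparisons: ``1 - (1 - p)^m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def compare_groups(groups: dict[str, np.ndarray], procedure: str = "auto",
                   equal_var: bool = True) -> ComparisonResult:
    """Hypothesis test between groups.

    Two groups: two-sided Student's t (equal variance by default; set
    ``equal_var=False`` for Welch). Three or more: one-way ANOVA followed by
    Tukey HSD (``procedure="tukey"``/"auto") or Šidák-adjusted pairwise t
    tests (``procedure="sidak"``). Every pair row carries raw p, adjusted p
    and the significance stars of the adjusted p.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2; variance-based tests need n >= 2")

    if len(labels) == 2:
        t, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        pairs = pd.DataFrame([{
            "group_a": labels[0], "group_b": labels[1],
            "p_raw": float(p), "p_adj": float(p),
            "stars": significance_stars(float(p)),
        }])
        return ComparisonResult(test="t" if equal_var else "welch-t",
                                statistic=float(t), p=float(p), pairs=pairs)

    f, p_omni = sps.f_oneway(*arrays)
    rows = []
    if procedure in ("auto", "tukey"):
        tk = sps.tukey_hsd(*arrays)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                _, praw = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
                p_adj = float(tk.pvalue[i, j])
                rows.append({"group_a": labels[i], "group_b": labels[j],
                             "p_raw": float(praw), "p_adj": p_adj,
                             "stars": significance_stars(p_adj)})
        test = "anova+tukey"
    elif procedure == "sidak":
        m = len(labels) * (len(labels) - 1) // 2
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                _, praw = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
                padj = float(sidak_adjust(float(praw), m))
                rows.append({"group_a": labels[i], "group_b": labels[j],
                             "p_raw": float(praw), "p_adj": padj,
                             "stars": significance_stars(padj)})
        test = "anova+sidak"
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    return ComparisonResult(test=test, statistic=float(f), p=float(p_omni),
                            pairs=pd.DataFrame(rows))


def flag_outliers(values, k: float = 3.5) -> np.ndarray:
    """Robust outlier flags: modified z-score |x - median| / (1.4826 MAD) > k.

    Flags only — removal is an explicit caller decision, never silent. For
    all-equal samples (MAD = 0) nothing is flagged unless a value differs
    from the median at all, in which case the flag falls back to exact
    inequality scaled by machine precision.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("outlier flagging needs n >= 5")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        spread = np.abs(v - med)
        return spread > (1e3 * np.finfo(float).eps * max(1.0, np.abs(med)))
    z = np.abs(v - med) / (1.4826 * mad)
    return z > k
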