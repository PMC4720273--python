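"""Two-sample tests and box-plot summaries for the class contrasts.

Every contrast in the pipeline (bound vs unbound diversity, HTG vs Core,
class I vs class II intergenics, expression levels) reduces to unpaired
two-sample comparisons: the Wilcoxon rank-sum (Mann-Whitney) test for
location, Levene's test for spread, the two-sided Kolmogorov-Smirnov test
for whole-distribution differences, and Fisher's exact test for 2x2
category counts.  Raw p-values are reported (no multiple-testing
correction by default, Benjamini-Hochberg available as an option).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BoxSummary",
    "wilcoxon_rank_sum",
    "levene_test",
    "ks_two_sample",
    "fisher_exact",
    "box_summary",
    "grouped_contrast",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    alternative: str = "two-sided"
    extra: Optional[Dict[str, float]] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


def _asarray(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample {name!r}")
    return arr


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration of the U distribution when n_x + n_y <= 12 and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    xa, ya = _asarray(x, "x"), _asarray(y, "y")
    pooled = np.concatenate([xa, ya])
    exact = (xa.size + ya.size <= 12) and (np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
                      xa.size, ya.size, extra={"exact": float(exact)})


def levene_test(x: Sequence[float], y: Sequence[float], *, center: str = "mean") -> TestResult:
    """Classic (mean-centered) Levene W with F(k-1, N-k) reference.

    center="median" gives the Brown-Forsythe variant.
    """
    xa, ya = _asarray(x, "x"), _asarray(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs >= 2 observations")
    cfun = np.mean if center == "mean" else np.median
    if np.allclose(np.abs(xa - cfun(xa)), 0) and np.allclose(np.abs(ya - cfun(ya)), 0):
        raise ValueError("zero within-group deviation in all groups; W undefined")
    stat, p = sps.levene(xa, ya, center=center)
    return TestResult("levene", float(stat), float(p), xa.size, ya.size,
                      extra={"df1": 1.0, "df2": float(xa.size + ya.size - 2)})


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p."""
    xa, ya = _asarray(x, "x"), _asarray(y, "y")
    res = sps.ks_2samp(xa, ya, alternative="two-sided", method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue),
                      xa.size, ya.size)


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test for a 2x2 table; odds ratio reported."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p),
                      int(t[0].sum()), int(t[1].sum()),
                      extra={"odds_ratio": float(odds)})


def box_summary(x: Sequence[float]) -> BoxSummary:
    """Median, quartiles (linear interpolation between order statistics)
    and whiskers at the most extreme points within 1.5 IQR of the box."""
    xa = _asarray(x, "x")
    q1, med, q3 = np.quantile(xa, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = xa[(xa >= lo_fence) & (xa <= hi_fence)]
    # quartiles themselves are always inside the fences, so `inside` is
    # non-empty for any sample
    return BoxSummary(float(med), float(q1), float(q3),
                      float(inside.min()), float(inside.max()), int(xa.size))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out


def grouped_contrast(records: pd.DataFrame, *, value: str, group: str,
                     strata: Optional[Sequence[str]] = None,
                     adjust: bool = False) -> pd.DataFrame:
    """Per-stratum two-group comparison table.

    For every combination of the ``strata`` label columns (or a single
    pooled stratum when None) the two levels of ``group`` are compared
    with the rank-sum and Levene tests and summarised with box statistics.
    Strata with an empty side are skipped with a warning.
    """
    df = records.dropna(subset=[value])
    levels = sorted(df[group].unique())
    if len(levels) != 2:
        raise ValueError(f"group column {group!r} must have exactly 2 levels, got {levels}")
    lo, hi = levels
    if strata:
        groups = df.groupby(list(strata), sort=True)
        items = [("|".join(map(str, k if isinstance(k, tuple) else (k,))), sub)
                 for k, sub in groups]
    else:
        items = [("all", df)]
    rows = []
    for name, sub in items:
        x = sub.loc[sub[group] == hi, value].to_numpy()
        y = sub.loc[sub[group] == lo, value].to_numpy()
        if x.size < 1 or y.size < 1:
            warnings.warn(f"stratum {name!r}: a side is empty; skipped")
            continue
        row: Dict[str, object] = {"stratum": name, "group_hi": hi, "group_lo": lo,
                                  "n_hi": x.size, "n_lo": y.size}
        w = wilcoxon_rank_sum(x, y)
        row.update(wilcoxon_stat=w.statistic, wilcoxon_p=w.p_value)
        try:
            lv = levene_test(x, y)
            row.update(levene_stat=lv.statistic, levene_p=lv.p_value)
        except ValueError:
            row.update(levene_stat=np.nan, levene_p=np.nan)
        for tag, arr in (("hi", x), ("lo", y)):
            b = box_summary(arr)
            row.update({f"median_{tag}": b.median, f"q1_{tag}": b.q1, f"q3_{tag}": b.q3,
                        f"whisk_lo_{tag}": b.whisker_low, f"whisk_hi_{tag}": b.whisker_high})
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["wilcoxon_p_bh"] = benjamini_hochberg(out["wilcoxon_p"].to_numpy())
    return out
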