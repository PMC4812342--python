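"""Summary statistics over pipeline outputs: count-bias chi-square tests,
peak-time uniformity tests, epoch firing-rate contrasts, and behavioral
accuracy / reaction-time tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import RT_TRUNC_HI


@dataclass
class CountComparison:
    counts: tuple[int, int]
    statistic: float
    df: int
    p: float


def count_bias_test(n1: int, n2: int) -> CountComparison:
    """One-df goodness-of-fit chi-square of two counts against equality.

    Statistic = sum((O - E)^2 / E) with E = (n1 + n2) / 2.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    total = n1 + n2
    if total == 0:
        raise ValueError("both counts are zero")
    e = total / 2.0
    chi2 = (n1 - e) ** 2 / e + (n2 - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1))
    return CountComparison(counts=(n1, n2), statistic=float(chi2), df=1, p=p)


def uniformity_test(peak_times: np.ndarray,
                    window: tuple[float, float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against uniformity on ``window``."""
    t = np.asarray(peak_times, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 peak times")
    lo, hi = window
    if (t < lo).any() or (t > hi).any():
        raise ValueError("peak times outside the analysis window")
    res = stats.kstest(t, stats.uniform(loc=lo, scale=hi - lo).cdf)
    return float(res.statistic), float(res.pvalue)


def epoch_means(values: np.ndarray, bin_centers: np.ndarray,
                epoch: tuple[float, float]) -> np.ndarray:
    """Mean over the bins whose centers fall inside [start, end)."""
    lo, hi = epoch
    sel = (bin_centers >= lo) & (bin_centers < hi)
    if not sel.any():
        raise ValueError("epoch lies outside the analysis window")
    return np.asarray(values, dtype=float)[..., sel].mean(axis=-1)


def epoch_contrast(cond_a: np.ndarray, cond_b: np.ndarray,
                   paired: bool = True) -> tuple[float, float]:
    """t-test of per-unit epoch means between two conditions or groups.

    ``paired`` compares the two conditions within the same units
    (paired t-test); otherwise the two arrays are independent unit groups.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise ValueError("paired contrast needs >= 2 matched units")
        t, p = stats.ttest_rel(a, b)
    else:
        if min(a.size, b.size) < 2:
            raise ValueError("unpaired contrast needs >= 2 units per group")
        t, p = stats.ttest_ind(a, b)
    if np.isnan(t):   # zero variance in the differences
        t, p = 0.0, 1.0
    return float(t), float(p)


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n on the 0-100 scale, rounded to printed precision."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)


def unit_count_table(labels_by_unit: dict[int, str],
                     cell_types: dict[int, str]) -> pd.DataFrame:
    """Counts and percentages of preference categories by cell type.

    ``labels_by_unit`` maps unit_id to one of difficulty/location/both/none.
    Percentages are within cell type; an 'all' row pools both types.
    """
    cats = ["difficulty", "location", "both", "none"]
    rows = []
    groups = {"RS": [], "FS": []}
    for uid, lab in labels_by_unit.items():
        groups[cell_types[uid]].append(lab)
    groups["all"] = groups["RS"] + groups["FS"]
    for ct, labs in groups.items():
        n = len(labs)
        for cat in cats:
            k = sum(1 for x in labs if x == cat)
            rows.append((ct, cat, k, proportion_pct(k, n) if n else np.nan))
        rows.append((ct, "any", sum(1 for x in labs if x != "none"),
                     proportion_pct(sum(1 for x in labs if x != "none"), n)
                     if n else np.nan))
    return pd.DataFrame(rows, columns=["cell_type", "category", "count",
                                       "percent"])


@dataclass
class BehaviorSummary:
    table: pd.DataFrame                       # per condition level
    rt_difficulty_test: tuple[float, float]   # unpaired t, easy vs hard RT
    accuracy_difficulty_test: tuple[float, float] | None  # paired across sessions


def behavior_summary(trials: pd.DataFrame,
                     session_col: str | None = "session") -> BehaviorSummary:
    """Accuracy and reaction-time summary per condition.

    Accuracy = correct/total x 100 per condition level.  Reaction times to
    touch (t_touch - t_init) and to drink (t_reward - t_touch) are averaged
    over correct trials only, excluding RTs above 15 s.  The difficulty RT
    contrast is an unpaired t-test across trials; the accuracy contrast is a
    paired t-test across sessions when a session column is present (flagged
    None with fewer than 2 sessions).
    """
    if trials.empty:
        raise ValueError("empty trial table")
    df = trials.copy()
    df["rt_touch"] = df["t_touch"] - df["t_init"]
    df["rt_drink"] = df["t_reward"] - df["t_touch"]
    df = df[df["rt_touch"] <= RT_TRUNC_HI]

    rows = []
    for var, codes in (("difficulty", {-1: "easy", +1: "hard"}),
                       ("location", {-1: "left", +1: "right"})):
        for code, name in codes.items():
            sub = df[df[var] == code]
            corr = sub[sub["correct"]]
            rows.append({
                "variable": var, "level": name, "code": code,
                "n_trials": len(sub),
                "accuracy_pct": (100.0 * sub["correct"].mean()
                                 if len(sub) else np.nan),
                "rt_touch_mean": corr["rt_touch"].mean(),
                "rt_touch_sem": corr["rt_touch"].sem(),
                "rt_drink_mean": corr["rt_drink"].mean(),
                "rt_drink_sem": corr["rt_drink"].sem(),
            })
    table = pd.DataFrame(rows)

    corr = df[df["correct"]]
    easy = corr.loc[corr["difficulty"] == -1, "rt_touch"]
    hard = corr.loc[corr["difficulty"] == +1, "rt_touch"]
    if min(len(easy), len(hard)) >= 2:
        t, p = stats.ttest_ind(hard, easy)
        rt_test = (float(t), float(p))
    else:
        rt_test = (np.nan, np.nan)

    acc_test = None
    if session_col is not None and session_col in df.columns:
        per = df.groupby([session_col, "difficulty"])["correct"].mean().unstack()
        if per.shape[0] >= 2 and not per.isna().any().any():
            t, p = stats.ttest_rel(per[-1], per[1])
            acc_test = (float(t), float(p))
    return BehaviorSummary(table=table, rt_difficulty_test=rt_test,
                           accuracy_difficulty_test=acc_test)
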