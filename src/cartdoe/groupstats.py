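"""Two-condition comparisons for report tables.

Pairwise pooled/Welch t-tests with a Brown-Forsythe variance pre-check and
the conventional significance-star notation. Two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


class StatsError(ValueError):
    pass


def stars(p_value: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if not 0.0 <= p_value <= 1.0:
        raise StatsError(f"p-value outside [0, 1]: {p_value}")
    for threshold, mark in STAR_THRESHOLDS:
        if p_value < threshold:
            return mark
    return "ns"


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    test_used: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    def to_row(self) -> dict:
        a, b = self.group_labels
        return {
            "group_a": a, "group_b": b,
            "n_a": self.n[0], "n_b": self.n[1],
            "mean_a": self.means[0], "mean_b": self.means[1],
            "sd_a": self.sds[0], "sd_b": self.sds[1],
            "test": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
        }


def _prepare(group_a, group_b, labels) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError(f"each group needs n >= 2 (got {a.size}, {b.size})")
    return a, b, tuple(labels)


def _comparison(a, b, labels, test, statistic, p) -> GroupComparison:
    return GroupComparison(
        group_labels=labels,
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        test_used=test,
        statistic=float(statistic),
        p_value=float(p),
    )


def pooled_t(group_a, group_b, labels=("a", "b")) -> GroupComparison:
    """Classical two-sample t-test with pooled variance, df = n_a + n_b - 2."""
    a, b, labels = _prepare(group_a, group_b, labels)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return _comparison(a, b, labels, "pooled-t", t, p)


def welch_t(group_a, group_b, labels=("a", "b")) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test."""
    a, b, labels = _prepare(group_a, group_b, labels)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return _comparison(a, b, labels, "welch-t", t, p)


def variance_check(group_a, group_b, labels=("a", "b")) -> GroupComparison:
    """Brown-Forsythe test (median-centred Levene) of equal variances."""
    a, b, labels = _prepare(group_a, group_b, labels)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise StatsError("both groups constant: variance test degenerate")
    w, p = stats.levene(a, b, center="median")
    return _comparison(a, b, labels, "brown-forsythe", w, p)


def compare_groups(group_a, group_b, labels=("a", "b"),
                   var_alpha: float = 0.05) -> GroupComparison:
    """Mean comparison with the test chosen by a variance pre-check:
    pooled t when Brown-Forsythe accepts equal variances, Welch otherwise."""
    var = variance_check(group_a, group_b, labels)
    if var.p_value < var_alpha:
        return welch_t(group_a, group_b, labels)
    return pooled_t(group_a, group_b, labels)


def comparison_table(data: pd.DataFrame, group_col: str, responses: list[str],
                     var_alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise comparison of two condition groups across several responses."""
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise StatsError(
            f"{group_col} must have exactly 2 levels for pairwise comparison "
            f"(got {levels})"
        )
    lo, hi = levels
    rows = []
    for resp in responses:
        a = data.loc[data[group_col] == lo, resp].to_numpy()
        b = data.loc[data[group_col] == hi, resp].to_numpy()
        cmp = compare_groups(a, b, labels=(f"{group_col}={lo}", f"{group_col}={hi}"),
                             var_alpha=var_alpha)
        row = {"response": resp}
        row.update(cmp.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
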