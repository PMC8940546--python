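"""Group summaries and two-independent-samples t comparisons for cohorts.

The comparison of interest is stable versus unstable knees on four
bone-tunnel angle variables.  Continuous variables are summarized as mean
+/- sample SD; categorical ones as count and percent (half-up rounding to
one decimal).  The default test is the pooled-variance Student t (the
conventional "independent-samples t-test"); Welch's variant is available
by flag.  All p-values are two-sided, significance is called at alpha =
0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from kneemech.errors import ValidationError
from kneemech.synthetic import ANGLE_VARIABLES

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    percent: Optional[float] = None

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError("group summary requires n > 0")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("SD must be >= 0")


def percent_half_up(count: int, total: int) -> float:
    """Percent of total, rounded half-up to one decimal (table formatting)."""
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(records: pd.DataFrame, variable: str, group: str) -> GroupSummary:
    """Mean/SD (continuous) or count/percent (categorical) for one group.

    The SD uses the n-1 denominator; a single record yields mean = value
    with the SD left undefined (None).
    """
    sub = records[records["group"] == group]
    if len(sub) == 0:
        raise ValidationError(f"no records in group {group!r}")
    values = sub[variable]
    if values.dtype.kind in "if":
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(sub) > 1 else None
        return GroupSummary(n=len(sub), mean=mean, sd=sd)
    # categorical: report the modal level's count/percent per level
    counts = values.value_counts()
    top = counts.index[0]
    return GroupSummary(n=len(sub), percent=percent_half_up(int(counts.iloc[0]), len(sub)))


def categorical_breakdown(records: pd.DataFrame, variable: str, group: str) -> dict:
    """Count and percent (one decimal, half-up) per level of a categorical."""
    sub = records[records["group"] == group]
    if len(sub) == 0:
        raise ValidationError(f"no records in group {group!r}")
    counts = sub[variable].value_counts()
    return {level: (int(c), percent_half_up(int(c), len(sub))) for level, c in counts.items()}


def two_sample_t(group_a, group_b, variant: str = "pooled"):
    """Two-sample t-test on raw values; returns (t, df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def summary_stat_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant: str = "pooled"):
    """Same test computed from group summary statistics only.

    Lets published mean/SD/n rows be compared directly without raw data.
    """
    for n in (n_a, n_b):
        if n < 2:
            raise ValidationError("each group needs n >= 2")
    for sd in (sd_a, sd_b):
        if sd < 0:
            raise ValidationError("SD must be >= 0")
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_cohort(records: pd.DataFrame, variables=ANGLE_VARIABLES,
                   group_a: str = "stable", group_b: str = "unstable",
                   variant: str = "pooled", alpha: float = ALPHA) -> pd.DataFrame:
    """Per-variable group summaries, t statistic, p and significance flag.

    One row per variable; ``significant`` is the boolean p < alpha.
    """
    for g in (group_a, group_b):
        if (records["group"] == g).sum() == 0:
            raise ValidationError(f"group {g!r} has no records")
    rows = []
    for var in variables:
        a = records.loc[records["group"] == group_a, var].to_numpy(dtype=float)
        b = records.loc[records["group"] == group_b, var].to_numpy(dtype=float)
        t, df, p = two_sample_t(a, b, variant=variant)
        rows.append({
            "variable": var,
            f"n_{group_a}": a.size,
            f"mean_{group_a}": float(a.mean()),
            f"sd_{group_a}": float(a.std(ddof=1)),
            f"n_{group_b}": b.size,
            f"mean_{group_b}": float(b.mean()),
            f"sd_{group_b}": float(b.std(ddof=1)),
            "t": t,
            "df": df,
            "p": p,
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
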