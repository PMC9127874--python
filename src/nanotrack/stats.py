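"""Condition-vs-control comparison: two-sample t-tests with star codes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = ["ConditionComparison", "compare_groups", "significance_code"]


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ConditionComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significance_code: str
    equal_var: bool


def compare_groups(
    values_a,
    values_b,
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = True,
) -> ConditionComparison:
    """Unpaired two-sample t-test (pooled-variance Student by default,
    Welch with ``equal_var=False``); means and sample SDs reported.

    No multiple-testing correction is applied.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(t), float(p)
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return ConditionComparison(
        label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(b.mean()), sd_b=float(np.std(b, ddof=1)),
        t_statistic=t, p_value=p, significance_code=significance_code(p),
        equal_var=equal_var,
    )
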