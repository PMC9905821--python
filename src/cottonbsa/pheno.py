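"""Descriptive phenotype statistics for parents and segregating populations.

Summaries follow the spreadsheet/SPSS conventions: bias-corrected sample
skewness and excess kurtosis (simple moment estimators behind a flag), and a
Welch two-sample t-test for the parental comparison with the usual
significance stars (* p<0.05, ** p<0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def summarize(values, bias_corrected: bool = True) -> dict:
    """Max, min, mean, skewness, and excess kurtosis of one trait vector.

    Skewness and kurtosis are reported as NaN when n < 4 or when the values
    are constant (zero variance).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: float("nan") for k in ("max", "min", "mean", "skew", "kurt")}
    out = {"max": float(v.max()), "min": float(v.min()), "mean": float(v.mean())}
    if v.size < 4 or np.ptp(v) == 0:
        out["skew"] = float("nan")
        out["kurt"] = float("nan")
    else:
        out["skew"] = float(sps.skew(v, bias=not bias_corrected))
        out["kurt"] = float(sps.kurtosis(v, fisher=True, bias=not bias_corrected))
    return out


def summary_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """One summary row per named population, in the layout of a trait table."""
    rows = [{"population": name, **summarize(vals)} for name, vals in groups.items()]
    return pd.DataFrame(rows, columns=["population", "max", "min", "mean", "skew", "kurt"])


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_parents(group_a, group_b) -> tuple[float, float, str]:
    """Welch two-sample t-test between two parent groups.

    Returns (t statistic, p-value, stars).  Two zero-variance groups with
    equal means give p = 1 (no evidence of difference); with different means
    they give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        t = float("inf") if a.mean() > b.mean() else float("-inf")
        return t, 0.0, "**"
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), significance_stars(float(p))
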