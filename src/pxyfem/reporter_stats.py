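"""Dual-reporter assay statistics: firefly normalisation and the t test.

Per-embryo nanoluciferase readings are normalised by the firefly reading of
the same embryo (a co-delivered transfection/injection control), then
compared between two groups with an unpaired two-tailed Student t test.
Pooled variance is the default (df = nA + nB - 2, matching the published
degrees of freedom); a Welch mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TTestResult", "normalize_reporter", "students_t_test", "group_summary"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p}


def normalize_reporter(
    table: pd.DataFrame,
    nanoluc_col: str = "nanoluc",
    firefly_col: str = "firefly",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add ``normalized = nanoluc / firefly``; exclude non-positive firefly rows.

    Returns ``(normalized_table, exclusion_log)``.  Rows whose firefly
    reading is zero or negative cannot be normalised; they are removed and
    reported in the exclusion log rather than silently dropped.
    """
    if table.empty:
        raise ValueError("empty assay table")
    for col in (nanoluc_col, firefly_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    bad = table[firefly_col] <= 0
    excluded = table[bad].copy()
    kept = table[~bad].copy()
    kept["normalized"] = kept[nanoluc_col] / kept[firefly_col]
    return kept, excluded


def students_t_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Unpaired two-tailed t test (pooled-variance Student by default).

    Raises on groups smaller than 2 or on zero pooled variance (degenerate
    input: a t statistic is undefined when both groups are constant).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if not welch:
        pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
        if pooled == 0:
            raise ValueError("zero pooled variance: degenerate input")
        res = stats.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    else:
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both groups: degenerate input")
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def group_summary(
    table: pd.DataFrame, group_col: str = "group", value_col: str = "normalized"
) -> pd.DataFrame:
    """Per-group n, mean and standard error of the normalised values."""
    g = table.groupby(group_col)[value_col]
    return pd.DataFrame(
        {"n": g.size(), "mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.size())}
    )
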