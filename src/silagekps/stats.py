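"""Correlation analysis of model KPS against annotation KPS.

For each model column of a KPS table the analysis reports: Shapiro-Wilk
normality of both samples (Pearson's correlation assumes bivariate
normality), the sample Pearson coefficient r with its two-tailed p-value
from the exact t transform

    t = r * sqrt(df / (1 - r^2)),   df = n - 2,

the explained variance 100 * r^2 in percent, and the ordinary
least-squares line relating the two.  With 17 processor-gap sequences
this is the familiar "r(15)" analysis of small paired samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "UndefinedStatisticError",
    "NormalityViolation",
    "CorrelationReport",
    "pearson",
    "shapiro_wilk",
    "linear_fit",
    "correlation_report",
]


class UndefinedStatisticError(ValueError):
    """Raised for inputs on which the statistic is undefined (constant
    vectors, too-small samples)."""


class NormalityViolation(RuntimeError):
    """Raised when a Shapiro-Wilk test rejects normality (p < alpha) for
    a sample entering a Pearson correlation and ``force`` is not set."""


@dataclass(frozen=True)
class CorrelationReport:
    """Full per-model analysis: normality, correlation and linear fit."""

    model: str
    n: int
    df: int
    r: float
    p_two_tailed: float
    r_squared_percent: float
    slope: float
    intercept: float
    shapiro_w_x: float
    shapiro_p_x: float
    shapiro_w_y: float
    shapiro_p_y: float


def _check_vector(x, name: str, min_n: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise UndefinedStatisticError(f"{name}: need a 1-d sample of length >= {min_n}")
    if not np.all(np.isfinite(x)):
        raise UndefinedStatisticError(f"{name}: non-finite values")
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError(f"{name}: constant sample")
    return x


def pearson(x, y) -> tuple[float, int, float]:
    """Sample Pearson correlation with exact-t two-tailed p-value.

    Returns ``(r, df, p)`` with ``df = n - 2``.  The p-value comes from
    the t distribution rather than a normal approximation, which matters
    at the small n this analysis runs at.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise UndefinedStatisticError("x and y must be paired (equal length)")
    n = x.size
    df = n - 2
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, df, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return r, df, p


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston's approximation, valid for
    3 <= n <= 5000)."""
    x = _check_vector(x, "sample")
    if x.size > 5000:
        raise UndefinedStatisticError("Shapiro-Wilk approximation valid only for n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least-squares line ``y = slope * x + intercept``."""
    x = _check_vector(x, "x", min_n=2)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UndefinedStatisticError("x and y must be paired (equal length)")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def correlation_report(
    kps_table: pd.DataFrame,
    model: str,
    annotation_column: str = "annotation",
    alpha: float = 0.05,
    force: bool = False,
) -> CorrelationReport:
    """Analyse one model column of a KPS table against the annotations.

    The model column is x, the annotation column is y (the ground truth
    whose variance the model is to explain).  If either sample fails the
    Shapiro-Wilk test at ``alpha`` the report refuses to quote Pearson's
    r — normality is a stated assumption — unless ``force`` is set.

    Raises
    ------
    annotations.ValidationError-like KeyError for a missing column;
    UndefinedStatisticError for incomplete (NaN) cells.
    """
    if model not in kps_table.columns:
        raise KeyError(f"model column {model!r} not in table")
    if annotation_column not in kps_table.columns:
        raise KeyError(f"annotation column {annotation_column!r} not in table")
    x = kps_table[model].to_numpy(dtype=float)
    y = kps_table[annotation_column].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        seqs = (
            kps_table.iloc[bad]["sequence_id"].tolist()
            if "sequence_id" in kps_table.columns
            else bad.tolist()
        )
        raise UndefinedStatisticError(f"missing KPS cells for sequences {seqs}")

    w_x, p_x = shapiro_wilk(x)
    w_y, p_y = shapiro_wilk(y)
    if (p_x < alpha or p_y < alpha) and not force:
        raise NormalityViolation(
            f"Shapiro-Wilk rejects normality (p_x={p_x:.4g}, p_y={p_y:.4g}); "
            "pass force=True to compute Pearson anyway"
        )
    r, df, p = pearson(x, y)
    slope, intercept = linear_fit(x, y)
    return CorrelationReport(
        model=model, n=x.size, df=df, r=r, p_two_tailed=p,
        r_squared_percent=100.0 * r * r, slope=slope, intercept=intercept,
        shapiro_w_x=w_x, shapiro_p_x=p_x, shapiro_w_y=w_y, shapiro_p_y=p_y,
    )
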