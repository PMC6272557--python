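"""Association between sweetness and the quality indicators.

Each of the four pharmacopoeia indicators is regressed on the
sucrose-equivalent sweetness index (indicator as response Y, sweetness
as predictor X) by ordinary least squares, with the Pearson correlation
r and its two-sided p-value from the exact t reference distribution
t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom. No
multiple-testing correction is applied: four raw per-indicator tests
are reported, as is conventional for this panel (see docs/methods.md).

The orientation is deliberately fixed as indicator-on-sweetness; the
inverse regression is not offered, to keep slopes comparable across
indicators and avoid silent misuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AssociationResult:
    """OLS line and correlation of one indicator against sweetness."""

    indicator: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; correlation undefined")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two nonconstant vectors."""
    x, y = _validate_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def fit_regression(
    x: Sequence[float], y: Sequence[float], indicator: str = ""
) -> AssociationResult:
    """OLS of indicator (y) on sweetness (x) with exact-t inference."""
    x, y = _validate_pair(x, y)
    fit = stats.linregress(x, y)
    return AssociationResult(
        indicator=indicator,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def association_table(
    sweetness: Sequence[float], indicators: pd.DataFrame
) -> pd.DataFrame:
    """Regress every indicator column on sweetness; one row per indicator."""
    rows = []
    for name in indicators.columns:
        res = fit_regression(sweetness, indicators[name].to_numpy(), indicator=name)
        rows.append(
            {
                "indicator": res.indicator,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.r,
                "p": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of a samples x variables table.

    Symmetric with exact unit diagonal; entries in [-1, 1]. A constant
    column is an error naming the column, not a silent NaN.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    constant = [c for c, col in zip(table.columns, X.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"constant column(s): {', '.join(map(str, constant))}")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=table.columns, columns=table.columns)
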