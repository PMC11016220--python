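"""Rubin's rules for combining estimates across multiple imputations.

The pooled point is the mean of the m per-imputation points; the total
variance is the mean within-imputation variance plus the between-imputation
variance inflated by the finite-m factor (1 + 1/m).  Confidence intervals
use Rubin's classical degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "rubin_pool"]


@dataclass
class PooledEstimate:
    point: float
    within: float               # W: mean per-imputation variance
    between: Optional[float]    # B: sample variance of points (None when m = 1)
    total: float                # T = W + (1 + 1/m) B
    df: float                   # Rubin's degrees of freedom (inf when B = 0)
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def rubin_pool(points: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> PooledEstimate:
    """Pool m point estimates with their within-imputation variances.

    ``df = (m - 1) (1 + W / ((1 + 1/m) B))^2`` when B > 0; with no
    between-imputation variance (or m = 1) the normal reference is used.
    """
    q = np.asarray(points, float)
    v = np.asarray(variances, float)
    if q.size == 0:
        raise ValueError("empty input")
    if q.shape != v.shape:
        raise ValueError("points and variances must have equal length")
    if (v < 0).any() or np.isnan(v).any():
        raise ValueError("variances must be finite and >= 0")
    m = int(q.size)

    if m == 1:
        warnings.warn("single imputation: total variance equals the "
                      "within-imputation variance", UserWarning, stacklevel=2)
        w_var = float(v[0])
        se = np.sqrt(w_var)
        z = stats.norm.ppf(1 - alpha / 2)
        return PooledEstimate(point=float(q[0]), within=w_var, between=None,
                              total=w_var, df=np.inf,
                              ci_low=float(q[0] - z * se),
                              ci_high=float(q[0] + z * se), m=1)

    point = float(q.mean())
    w_var = float(v.mean())
    b_var = float(q.var(ddof=1))
    total = w_var + (1.0 + 1.0 / m) * b_var
    if b_var > 0:
        with np.errstate(over="ignore"):
            df = float((m - 1) * (1.0 + np.float64(w_var)
                                  / ((1.0 + 1.0 / m) * np.float64(b_var))) ** 2)
        tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) \
            else stats.norm.ppf(1 - alpha / 2)
    else:
        df = np.inf
        tcrit = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(total)
    return PooledEstimate(point=point, within=w_var, between=b_var,
                          total=float(total), df=float(df),
                          ci_low=float(point - tcrit * se),
                          ci_high=float(point + tcrit * se), m=m)
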