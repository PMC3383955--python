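"""Simple-statistics kernel: closed-form OLS and the paired t-test.

These are deliberately small closed-form implementations (the quantities
they feed are 9-point condition-mean regressions and a 17-subject paired
comparison); they are cross-checked against independent normal-equation
and scipy oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["RegressionResult", "TTestResult", "ols", "paired_ttest"]

_TINY = float(np.finfo(np.float64).tiny)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df_num: int
    df_den: int
    p: float
    n: int
    slope_se: float = 0.0

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        tcrit = sps.t.ppf(0.5 + level / 2, self.df_den)
        return (self.slope - tcrit * self.slope_se,
                self.slope + tcrit * self.slope_se)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def ols(x, y) -> RegressionResult:
    """Simple linear regression y = intercept + slope * x.

    F is reported as (r2/(1-r2)) * df_den with df (1, n-2); a perfect
    fit yields F = inf and p clamped to the smallest positive float.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("constant predictor: regression undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    rss = max(syy - slope * sxy, 0.0)
    if syy > 0:
        r2 = 1.0 - rss / syy
    else:  # flat response fitted exactly by slope 0
        r2 = 1.0
    df_den = n - 2
    se = float(np.sqrt((rss / df_den) / sxx))
    # tolerate tiny negative rounding of 1 - r2
    if r2 >= 1.0 - 1e-14:
        r2 = 1.0
        f = np.inf
        p = _TINY
    else:
        f = (r2 / (1.0 - r2)) * df_den
        p = float(np.clip(sps.f.sf(f, 1, df_den), _TINY, 1.0))
    return RegressionResult(
        slope=float(slope), intercept=intercept, r2=float(r2),
        f_stat=float(f), df_num=1, df_den=df_den, p=p, n=n, slope_se=se,
    )


def paired_ttest(a, b) -> TTestResult:
    """Two-tailed paired t-test; df = n - 1.

    Zero within-pair variance is flagged degenerate: t = 0 (p = 1) when
    the arrays are identical, t = +/-inf (p -> 0) for a constant nonzero
    difference.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired arrays must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(
            t=float(np.sign(md)) * np.inf, df=df, p=_TINY, degenerate=True
        )
    t = md / (sd / np.sqrt(n))
    p = float(np.clip(2.0 * sps.t.sf(abs(t), df), _TINY, 1.0))
    return TTestResult(t=float(t), df=df, p=p)
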