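"""Method-comparison statistics: Deming, Passing-Bablok, Bland-Altman.

Two consensus curves (a "reference" and a "test" method) are compared on
paired responses.  Deming regression is the closed-form errors-in-variables
line with error-variance ratio lambda (y:x) and jackknife uncertainty;
Passing-Bablok is the nonparametric shifted-median-of-pairwise-slopes line
with rank-based confidence intervals; Bland-Altman summarises the paired
differences by their mean (bias) and 1.96-SD limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "PairedResponses",
    "DemingResult",
    "PassingBablokResult",
    "BlandAltmanResult",
    "MethodComparisonResult",
    "deming_fit",
    "passing_bablok_fit",
    "bland_altman",
    "compare_methods",
]


@dataclass(frozen=True)
class PairedResponses:
    """Paired reference (x) and test (y) values for the same items."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        xa = np.asarray(self.x, dtype=float)
        ya = np.asarray(self.y, dtype=float)
        if xa.shape != ya.shape or xa.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "x", xa)
        object.__setattr__(self, "y", ya)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    lam: float
    n: int


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    n: int
    n_slopes: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    differences: np.ndarray
    means: np.ndarray


@dataclass(frozen=True)
class MethodComparisonResult:
    deming: DemingResult
    passing_bablok: PassingBablokResult
    bland_altman: BlandAltmanResult
    data: PairedResponses

    def to_dict(self) -> dict:
        d, pb, ba = self.deming, self.passing_bablok, self.bland_altman
        return {
            "deming": {
                "slope": d.slope,
                "intercept": d.intercept,
                "se_slope": d.se_slope,
                "se_intercept": d.se_intercept,
                "ci95_slope": list(d.ci95_slope),
                "ci95_intercept": list(d.ci95_intercept),
                "lambda": d.lam,
            },
            "passing_bablok": {
                "slope": pb.slope,
                "intercept": pb.intercept,
                "ci95_slope": list(pb.ci95_slope),
                "ci95_intercept": list(pb.ci95_intercept),
            },
            "bland_altman": {
                "bias": ba.bias,
                "sd_diff": ba.sd_diff,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
            },
            "n": self.data.n,
        }


def _deming_slope_intercept(
    x: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    if sxy == 0.0:
        if syy == lam * sxx:
            raise DegenerateInputError(
                "indeterminate orientation: s_xy = 0 and s_yy = lambda*s_xx"
            )
        if syy < lam * sxx:
            return 0.0, ym  # flat line is the minimiser
        raise DegenerateInputError("vertical orientation: s_xy = 0, s_yy > lambda*s_xx")
    disc = (syy - lam * sxx) ** 2 + 4.0 * lam * sxy**2
    slope = (syy - lam * sxx + math.sqrt(disc)) / (2.0 * sxy)
    return slope, ym - slope * xm


def deming_fit(data: PairedResponses, lam: float = 1.0) -> DemingResult:
    """Errors-in-variables straight line with variance ratio lambda (y:x).

    The closed-form slope minimises the weighted orthogonal residual sum
    sum (y - a x - b)^2 / (lambda + a^2); standard errors come from the
    leave-one-out jackknife and the 95% CIs use the t quantile with n-2 df.
    """
    if data.n < 3:
        raise DegenerateInputError(f"Deming fit needs n >= 3, got {data.n}")
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    x, y, n = data.x, data.y, data.n
    slope, intercept = _deming_slope_intercept(x, y, lam)
    loo = np.empty((n, 2))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        loo[i] = _deming_slope_intercept(x[mask], y[mask], lam)
        mask[i] = True
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    tq = stats.t.ppf(0.975, n - 2)
    return DemingResult(
        slope=slope,
        intercept=intercept,
        se_slope=float(se[0]),
        se_intercept=float(se[1]),
        ci95_slope=(slope - tq * se[0], slope + tq * se[0]),
        ci95_intercept=(intercept - tq * se[1], intercept + tq * se[1]),
        lam=lam,
        n=n,
    )


def passing_bablok_fit(data: PairedResponses) -> PassingBablokResult:
    """Nonparametric line from the shifted median of pairwise slopes.

    All C(n,2) slopes S_ij are formed, skipping pairs with equal x
    (undefined) and slopes exactly equal to -1; the estimate is the median
    shifted by K = #{S_ij < -1}, which makes the fit invariant to swapping
    the roles of x and y.  Even slope counts take the lower median.  The CI
    comes from the rank-based normal approximation with
    w = 1.96 * sqrt(n(n-1)(2n+5)/18).
    """
    x, y, n = data.x, data.y, data.n
    if n < 3:
        raise DegenerateInputError(f"Passing-Bablok needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all x identical; slope undefined")
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            if dx == 0:
                continue
            s = (y[j] - y[i]) / dx
            if s == -1.0:
                continue
            slopes.append(s)
    big_n = len(slopes)
    if big_n < 3:
        raise DegenerateInputError(f"only {big_n} valid pairwise slopes")
    s_sorted = np.sort(slopes)
    k_off = int(np.sum(s_sorted < -1.0))

    def shifted(idx_1based: int) -> float:
        return float(s_sorted[np.clip(idx_1based + k_off - 1, 0, big_n - 1)])

    if big_n % 2 == 1:
        slope = shifted((big_n + 1) // 2)
    else:
        slope = shifted(big_n // 2)  # low-median convention
    z = stats.norm.ppf(0.975)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    slope_lo, slope_hi = shifted(m1), shifted(m2)
    intercept = float(np.median(y - slope * x))
    int_bounds = sorted(
        (float(np.median(y - slope_hi * x)), float(np.median(y - slope_lo * x)))
    )
    return PassingBablokResult(
        slope=slope,
        intercept=intercept,
        ci95_slope=(slope_lo, slope_hi),
        ci95_intercept=(int_bounds[0], int_bounds[1]),
        n=n,
        n_slopes=big_n,
    )


def bland_altman(data: PairedResponses) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of the paired differences."""
    if data.n < 2:
        raise DegenerateInputError(f"Bland-Altman needs n >= 2, got {data.n}")
    d = data.y - data.x
    means = (data.x + data.y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        differences=d,
        means=means,
    )


def compare_methods(data: PairedResponses, lam: float = 1.0) -> MethodComparisonResult:
    """All three agreement analyses on one paired dataset."""
    return MethodComparisonResult(
        deming=deming_fit(data, lam=lam),
        passing_bablok=passing_bablok_fit(data),
        bland_altman=bland_altman(data),
        data=data,
    )
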