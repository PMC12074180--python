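"""Statistical equivalence of calibration curves and consensus fitting.

A set of m curves is "equivalent" when one shared straight line describes all
of their points as well as m individual lines do, judged by the extra
sum-of-squares F test on the two nested OLS models.  Equivalent sets are
collapsed into a single consensus curve fitted to the pooled points, which
then serves for quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CalibrationCurve, LinearFit, fit_ols, _fit_xy
from .errors import DegenerateInputError

__all__ = ["EquivalenceResult", "extra_ss_f_test", "fit_consensus"]


@dataclass(frozen=True)
class EquivalenceResult:
    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    equivalent: bool
    alpha: float
    pooled_fit: LinearFit
    separate_fits: tuple[LinearFit, ...]

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_numerator": self.df_numerator,
            "df_denominator": self.df_denominator,
            "p_value": self.p_value,
            "equivalent": self.equivalent,
            "alpha": self.alpha,
            "pooled_equation": self.pooled_fit.equation(),
        }


def extra_ss_f_test(
    curves: list[CalibrationCurve], alpha: float = 0.05
) -> EquivalenceResult:
    """Extra sum-of-squares F test for a shared (slope, intercept).

    Null model: one line fitted to all points pooled (RSS0, N-2 df).
    Alternative: an individual line per curve (RSS1 = sum of per-curve RSS,
    N-2m df).  F = [(RSS0-RSS1)/(2(m-1))] / [RSS1/(N-2m)]; small p-values
    mean the curves differ and no consensus line should be used.
    """
    m = len(curves)
    if m < 2:
        raise DegenerateInputError("equivalence test needs >=2 curves")
    separate = tuple(fit_ols(c) for c in curves)
    pooled = fit_consensus(curves)
    n_total = sum(f.n for f in separate)
    df1 = n_total - 2 * m
    df0 = n_total - 2
    dfn = df0 - df1  # = 2 (m - 1)
    if df1 < 1:
        raise DegenerateInputError(
            f"insufficient residual df: N={n_total}, m={m} leaves {df1}"
        )
    rss1 = sum(f.rss for f in separate)
    rss0 = pooled.rss
    extra = max(rss0 - rss1, 0.0)  # clamp tiny negative rounding noise
    if rss1 == 0.0:
        f_stat = 0.0 if extra == 0.0 else float("inf")
        p = 1.0 if extra == 0.0 else 0.0
    else:
        f_stat = (extra / dfn) / (rss1 / df1)
        p = float(stats.f.sf(f_stat, dfn, df1))
    return EquivalenceResult(
        f_statistic=float(f_stat),
        df_numerator=dfn,
        df_denominator=df1,
        p_value=p,
        equivalent=p >= alpha,
        alpha=alpha,
        pooled_fit=pooled,
        separate_fits=separate,
    )


def fit_consensus(curves: list[CalibrationCurve]) -> LinearFit:
    """OLS fit on the union of all points of the member curves.

    Same contract as the per-curve fit; intended for curve sets already
    judged equivalent (the workflow enforces that ordering, not this
    function).
    """
    if not curves:
        raise DegenerateInputError("consensus fit needs >=1 curve")
    x = np.concatenate([c.levels for c in curves])
    y = np.concatenate([c.responses for c in curves])
    if len(set(x.tolist())) < 3:
        raise DegenerateInputError("pooled design needs >=3 distinct levels")
    return _fit_xy(x, y)
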