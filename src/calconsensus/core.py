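"""Core data model and single-curve statistics for fortified calibration data.

A fortified (matrix-spiked) calibration curve relates the nominal analyte
concentration in a blank matrix (ng g^-1) to the measured analyte/internal-
standard peak-area ratio.  This module holds the curve data model, ordinary
least-squares fitting with full uncertainty reporting, residual diagnostics,
and the bioanalytical validation metrics built on single curves: LOD/LOQ from
the intercept standard error, recovery/precision tables, back-calculation,
matrix effect, chromatographic capacity/selectivity factors and the
threshold pass/fail rules for selectivity, IS interference and carryover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, SingularDesignError

__all__ = [
    "LEVEL_GRID",
    "CalibrationPoint",
    "CalibrationCurve",
    "LinearFit",
    "ChromFactors",
    "RecoveryRow",
    "RuleFlags",
    "ValidationReport",
    "ResidualDiagnostics",
    "fit_ols",
    "origin_inclusion",
    "residual_diagnostics",
    "se_from_ci",
    "lod_loq",
    "percent_recovery",
    "accuracy_table",
    "back_calc",
    "back_calc_error",
    "matrix_effect",
    "chrom_factors",
    "selectivity_factor",
    "threshold_rules",
]

#: Default 8-point fortification grid (ng g^-1), zero level excluded.
LEVEL_GRID: tuple[float, ...] = (2.5, 5.0, 7.5, 10.0, 12.0, 15.0, 16.0, 20.0)


@dataclass(frozen=True)
class CalibrationPoint:
    """One fortified measurement: nominal level vs analyte/IS area ratio.

    The response may be negative (ion-suppressed matrices can invert the
    apparent response once the IS ratio is taken); the level may not be zero
    or negative — the blank level never enters the regression.
    """

    level: float
    response: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.level > 0):
            raise ValueError(f"level must be > 0, got {self.level!r}")
        if not math.isfinite(self.response):
            raise ValueError(f"response must be finite, got {self.response!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")


@dataclass(frozen=True)
class CalibrationCurve:
    """An ordered collection of points from one calibration run.

    ``group`` carries the batch label (typically the laboratory day) used
    downstream when clustering curves across runs.
    """

    curve_id: str
    group: str
    points: tuple[CalibrationPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) == 0:
            raise ValueError("curve must contain at least one point")

    @property
    def levels(self) -> np.ndarray:
        return np.array([p.level for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)

    @property
    def n_distinct_levels(self) -> int:
        return len({p.level for p in self.points})


@dataclass(frozen=True)
class LinearFit:
    """OLS estimates ``y = (a ± sa)·x + (b ± sb)`` with 95% Student-t CIs."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    r_squared: float
    residuals: np.ndarray
    rss: float
    df: int
    n: int

    def predict(self, level: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(level, dtype=float) + self.intercept

    def equation(self) -> str:
        return (
            f"y = ({self.slope:.4g} ± {self.se_slope:.2g})x "
            f"+ ({self.intercept:.4g} ± {self.se_intercept:.2g})"
        )


@dataclass(frozen=True)
class ChromFactors:
    """Retention characteristics: capacity factor k and selectivity alpha."""

    t_r: float
    t_0: float
    k: float
    alpha: float | None = None


@dataclass(frozen=True)
class RecoveryRow:
    """One accuracy-table row at a nominal QC level (full precision)."""

    level_label: str
    nominal: float
    mean: float
    rsd_pct: float
    rec_pct: float
    rec_ci95: tuple[float, float]
    n: int

    def rounded(self) -> dict:
        """Display rounding: mean 2 dp, %RSD 1 dp, %Rec integer."""
        half = (self.rec_ci95[1] - self.rec_ci95[0]) / 2
        return {
            "level": self.level_label,
            "nominal": self.nominal,
            "mean": round(self.mean, 2),
            "rsd_pct": round(self.rsd_pct, 1),
            "rec_pct": round(self.rec_pct),
            "rec_ci95_halfwidth": round(half, 1),
            "n": self.n,
        }


@dataclass(frozen=True)
class RuleFlags:
    """Pass/fail threshold rules with the measured values that drove them."""

    selectivity_pass: bool
    blank_to_lloq_ratio: float
    is_interference_pass: bool
    is_blank_to_is_ratio: float
    carryover_pass: bool
    carryover_signal: float
    lod_signal: float


@dataclass(frozen=True)
class ValidationReport:
    """Bundle of single-method validation outputs."""

    lod: float
    loq: float
    recovery_rows: tuple[RecoveryRow, ...]
    matrix_effect_pct: float | None = None
    strong_matrix_effect: bool | None = None
    rule_flags: RuleFlags | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "lod": self.lod,
            "loq": self.loq,
            "recovery": [r.rounded() for r in self.recovery_rows],
        }
        if self.matrix_effect_pct is not None:
            out["matrix_effect_pct"] = self.matrix_effect_pct
            out["strong_matrix_effect"] = self.strong_matrix_effect
        if self.rule_flags is not None:
            f = self.rule_flags
            out["rules"] = {
                "selectivity_pass": f.selectivity_pass,
                "blank_to_lloq_ratio": f.blank_to_lloq_ratio,
                "is_interference_pass": f.is_interference_pass,
                "is_blank_to_is_ratio": f.is_blank_to_is_ratio,
                "carryover_pass": f.carryover_pass,
            }
        return out


@dataclass(frozen=True)
class ResidualDiagnostics:
    """QQ coordinates, fitted-vs-residual pairs and an omnibus normality p."""

    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    normality_p: float
    normality_test: str


# ---------------------------------------------------------------------------
# fitting


def fit_ols(curve: CalibrationCurve) -> LinearFit:
    """Unweighted least-squares line through a calibration curve.

    The fit is never forced through the origin; confidence intervals use the
    Student-t quantile with n-2 degrees of freedom.  Requires at least three
    distinct levels.
    """
    x = curve.levels
    y = curve.responses
    if np.ptp(x) == 0:
        raise SingularDesignError(
            f"curve {curve.curve_id!r}: all levels identical ({x[0]})"
        )
    if curve.n_distinct_levels < 3:
        raise DegenerateInputError(
            f"curve {curve.curve_id!r}: needs >=3 distinct levels, "
            f"got {curve.n_distinct_levels}"
        )
    return _fit_xy(x, y)


def _fit_xy(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS on raw arrays; shared by per-curve and pooled (consensus) fits."""
    n = len(x)
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    intercept, slope = res.params
    se_intercept, se_slope = res.bse
    ci = res.conf_int(alpha=0.05)
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    # tss == 0 only for a constant response, where OLS is exact: R^2 := 1.
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        ci95_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(r2),
        residuals=np.asarray(res.resid, dtype=float),
        rss=rss,
        df=int(res.df_resid),
        n=n,
    )


def origin_inclusion(fit: LinearFit) -> tuple[bool, tuple[float, float]]:
    """Whether the 95% CI of the intercept brackets zero.

    A curve "passes through the origin" in the regulatory sense when zero is
    inside the interval; the interval used is returned for reporting.
    """
    lo, hi = fit.ci95_intercept
    return (lo <= 0.0 <= hi), (lo, hi)


def residual_diagnostics(fit: LinearFit, levels: Sequence[float] | None = None) -> ResidualDiagnostics:
    """QQ coordinates, fitted-vs-residual pairs and a normality p-value.

    Uses Shapiro-Wilk below n=20 and the D'Agostino-Pearson omnibus test at
    n>=20 (the omnibus moments are unstable in very small samples).
    """
    r = np.asarray(fit.residuals, dtype=float)
    n = len(r)
    if n < 4:
        raise DegenerateInputError(f"residual diagnostics need n >= 4, got {n}")
    (theo, sample), _ = stats.probplot(r, dist="norm")
    if levels is not None:
        fitted = fit.predict(np.asarray(levels, dtype=float))
    else:
        fitted = np.asarray([], dtype=float)
    # near-exact fits leave only rounding noise; no normality question arises
    if np.ptp(r) <= 1e-12 * max(1.0, float(np.abs(r).max())):
        test_name = "degenerate"
        p = 1.0
    elif n >= 20:
        test_name = "dagostino-pearson"
        p = float(stats.normaltest(r).pvalue)
    else:
        test_name = "shapiro-wilk"
        p = float(stats.shapiro(r).pvalue)
    return ResidualDiagnostics(
        qq_theoretical=theo,
        qq_sample=sample,
        fitted=np.asarray(fitted, dtype=float),
        residuals=r,
        normality_p=p,
        normality_test=test_name,
    )


# ---------------------------------------------------------------------------
# validation metrics


def se_from_ci(lower: float, upper: float) -> float:
    """Standard error recovered from a 95% CI: (upper - lower) / 3.92."""
    if upper < lower:
        raise ValueError(f"interval bounds out of order: ({lower}, {upper})")
    return (upper - lower) / 3.92


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from the calibration line.

    LOD = 3.3 * SD / |slope|, LOQ = 10 * SD / |slope| where SD is the
    standard error of the intercept.  The absolute slope keeps the limits
    positive for inverted-response (negative-slope) curves.
    """
    if slope == 0:
        raise ZeroDivisionError("slope must be non-zero for LOD/LOQ")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be >= 0")
    a = abs(slope)
    return 3.3 * sd_intercept / a, 10.0 * sd_intercept / a


def percent_recovery(mean: float, nominal: float) -> float:
    """Trueness as %Rec = 100 * mean / nominal."""
    if nominal <= 0:
        raise ValueError(f"nominal level must be > 0, got {nominal}")
    return 100.0 * mean / nominal


def accuracy_table(
    qc_replicates: Mapping[float, Sequence[float]],
    fit: LinearFit | None = None,
    labels: Mapping[float, str] | None = None,
) -> tuple[RecoveryRow, ...]:
    """Per-level precision (%RSD) and trueness (%Rec) with 95% CIs.

    ``qc_replicates`` maps each nominal level to its replicate values.  When
    ``fit`` is given the replicates are raw responses and are back-calculated
    through the fit first; otherwise they are already concentrations.  The
    %Rec confidence interval uses the Student-t quantile with n-1 df.
    """
    rows = []
    for nominal in qc_replicates:
        if nominal <= 0:
            raise ValueError(f"nominal level must be > 0, got {nominal}")
        vals = np.asarray(qc_replicates[nominal], dtype=float)
        if len(vals) < 2:
            raise DegenerateInputError(
                f"level {nominal}: need >=2 replicates, got {len(vals)}"
            )
        if fit is not None:
            vals = np.asarray([back_calc(fit, v) for v in vals])
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rsd = 100.0 * sd / mean if mean != 0 else float("inf")
        rec = percent_recovery(mean, nominal)
        tq = stats.t.ppf(0.975, n - 1)
        half = tq * 100.0 * sd / (math.sqrt(n) * nominal)
        label = labels.get(nominal, str(nominal)) if labels else str(nominal)
        rows.append(
            RecoveryRow(
                level_label=label,
                nominal=float(nominal),
                mean=mean,
                rsd_pct=rsd,
                rec_pct=rec,
                rec_ci95=(rec - half, rec + half),
                n=n,
            )
        )
    return tuple(rows)


def back_calc(fit: LinearFit, response: float) -> float:
    """Concentration read back from the calibration line: (y - b) / a."""
    if fit.slope == 0:
        raise ZeroDivisionError("cannot back-calculate with zero slope")
    return (response - fit.intercept) / fit.slope


def back_calc_error(fit: LinearFit, response: float, nominal: float) -> float:
    """Absolute percent relative error of the back-calculated concentration."""
    if nominal <= 0:
        raise ValueError(f"nominal must be > 0, got {nominal}")
    x_hat = back_calc(fit, response)
    return 100.0 * abs(x_hat - nominal) / nominal


def matrix_effect(slope_postspiked: float, slope_solvent: float) -> tuple[float, bool]:
    """Percent matrix effect from the post-spiked vs solvent slope ratio.

    %ME = 100 * (slope_postspiked / slope_solvent - 1).  Positive values
    indicate ionization enhancement, negative values suppression; the effect
    is flagged strong when |%ME| exceeds 20% (strictly).
    """
    if slope_solvent == 0:
        raise ZeroDivisionError("solvent-curve slope must be non-zero")
    me = 100.0 * (slope_postspiked / slope_solvent - 1.0)
    return me, abs(me) > 20.0


def chrom_factors(t_r: float, t_0: float) -> ChromFactors:
    """Capacity factor k = (t_r - t_0) / t_0 from retention and dead time."""
    if t_0 <= 0:
        raise ValueError(f"dead time must be > 0, got {t_0}")
    if t_r < t_0:
        raise ValueError("retention time must be >= dead time")
    return ChromFactors(t_r=t_r, t_0=t_0, k=(t_r - t_0) / t_0)


def selectivity_factor(k1: float, k2: float) -> float:
    """Selectivity alpha = k1 / k2 (later-eluting analyte over reference)."""
    if k2 == 0:
        raise ZeroDivisionError("reference capacity factor must be non-zero")
    return k1 / k2


def threshold_rules(
    blank_signal: float,
    lloq_signal: float,
    is_blank_signal: float,
    is_signal: float,
    carryover_signal: float,
    lod_signal: float,
) -> RuleFlags:
    """Regulatory pass/fail rules on blank, IS and carryover signals.

    Selectivity passes when the blank signal is strictly below 20% of the
    LLOQ signal; IS interference passes when the blank-in-IS-channel signal
    is at most 5% of the IS signal; carryover passes when the post-ULOQ blank
    signal is strictly below the LOD signal.
    """
    for name, v in (
        ("blank_signal", blank_signal),
        ("lloq_signal", lloq_signal),
        ("is_blank_signal", is_blank_signal),
        ("is_signal", is_signal),
        ("carryover_signal", carryover_signal),
        ("lod_signal", lod_signal),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return RuleFlags(
        selectivity_pass=blank_signal < 0.20 * lloq_signal,
        blank_to_lloq_ratio=blank_signal / lloq_signal if lloq_signal else float("inf"),
        is_interference_pass=is_blank_signal <= 0.05 * is_signal,
        is_blank_to_is_ratio=is_blank_signal / is_signal if is_signal else float("inf"),
        carryover_pass=carryover_signal < lod_signal,
        carryover_signal=carryover_signal,
        lod_signal=lod_signal,
    )
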