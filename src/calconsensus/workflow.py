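"""Orchestration of the consensus-calibration decision workflow.

Given several calibration curves (typically replicate curves from more than
one laboratory day), the pipeline decides how they may be unified for
quantification:

1. fit every curve by OLS;
2. test all curves jointly for equivalence (extra sum-of-squares F test) —
   if they are equivalent a single consensus curve is recommended and the
   analysis stops;
3. otherwise cluster the fitted (slope, intercept) parameters
   (Canberra/complete linkage) and select the cluster count by Dunn and
   silhouette indices;
4. test each cluster internally for equivalence and fit a consensus curve
   per equivalent cluster;
5. compare consensus curves pairwise (Deming, Passing-Bablok, Bland-Altman)
   on per-level mean responses;
6. profile the back-calculation error of every curve against its own and
   every other cluster's consensus;
7. recommend one of: single consensus, per-cluster consensus (a fresh curve
   per run group), or no consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusteringResult, CurveFeatures, select_k
from .compare import MethodComparisonResult, PairedResponses, compare_methods
from .core import CalibrationCurve, LinearFit, back_calc_error, fit_ols
from .equivalence import EquivalenceResult, extra_ss_f_test, fit_consensus
from .errors import DegenerateInputError
from .io import read_calibration_csv, write_report  # re-exported convenience

log = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "ClusterSummary",
    "WorkflowReport",
    "run_workflow",
    "read_calibration_csv",
    "write_report",
]

FEATURE_SETS = ("slope_intercept", "slope", "intercept")


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunable knobs; the defaults reproduce the reference two-day analysis."""

    alpha: float = 0.05
    lam: float = 1.0  # Deming error-variance ratio y:x
    feature_set: str = "slope_intercept"
    k_min: int = 2
    k_max: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        """Parse a key=value text config (# comments and blank lines allowed)."""
        kwargs: dict = {}
        casts = {"alpha": float, "lam": float, "feature_set": str, "k_min": int, "k_max": int}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = casts[key](val)
        return cls(**kwargs)


@dataclass(frozen=True)
class ClusterSummary:
    label: int
    curve_ids: tuple[str, ...]
    equivalence: EquivalenceResult | None  # None for singleton clusters
    consensus: LinearFit | None
    equivalent: bool

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "curve_ids": list(self.curve_ids),
            "equivalent": self.equivalent,
            "equivalence": None if self.equivalence is None else self.equivalence.to_dict(),
            "consensus_equation": None if self.consensus is None else self.consensus.equation(),
            "consensus_slope": None if self.consensus is None else self.consensus.slope,
            "consensus_intercept": None if self.consensus is None else self.consensus.intercept,
        }


@dataclass(frozen=True)
class WorkflowReport:
    curves: tuple[CalibrationCurve, ...]
    fits: dict[str, LinearFit]
    global_equivalence: EquivalenceResult
    clustering: ClusteringResult | None
    alt_clusterings: dict[str, ClusteringResult]
    clusters: tuple[ClusterSummary, ...]
    comparisons: dict[tuple[int, int], MethodComparisonResult]
    backcalc: pd.DataFrame | None
    recommendation: str  # single_consensus | per_cluster_consensus | no_consensus
    config: WorkflowConfig

    def fits_table(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            f = self.fits[c.curve_id]
            rows.append(
                {
                    "curve_id": c.curve_id,
                    "group": c.group,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "se_slope": f.se_slope,
                    "se_intercept": f.se_intercept,
                    "r_squared": f.r_squared,
                    "rss": f.rss,
                    "n": f.n,
                }
            )
        return pd.DataFrame(rows)

    def backcalc_summary(self) -> dict:
        """Mean/max |%RE| within own-cluster vs against other consensus curves."""
        if self.backcalc is None or not len(self.backcalc):
            return {}
        own = self.backcalc[self.backcalc.own]
        cross = self.backcalc[~self.backcalc.own]
        out = {
            "own_mean_pct": float(own.pct_error.mean()),
            "own_max_pct": float(own.pct_error.max()),
        }
        if len(cross):
            out["cross_mean_pct"] = float(cross.pct_error.mean())
            out["cross_max_pct"] = float(cross.pct_error.max())
        return out

    def to_dict(self) -> dict:
        return {
            "recommendation": self.recommendation,
            "config": {
                "alpha": self.config.alpha,
                "lambda": self.config.lam,
                "feature_set": self.config.feature_set,
                "k_range": [self.config.k_min, self.config.k_max],
            },
            "curves": [
                {"curve_id": c.curve_id, "group": c.group, "n_points": len(c.points)}
                for c in self.curves
            ],
            "fits": {cid: f.equation() for cid, f in self.fits.items()},
            "global_equivalence": self.global_equivalence.to_dict(),
            "clustering": None if self.clustering is None else self.clustering.to_dict(),
            "alt_clusterings": {k: v.to_dict() for k, v in self.alt_clusterings.items()},
            "clusters": [c.to_dict() for c in self.clusters],
            "comparisons": {
                f"{a}_vs_{b}": r.to_dict() for (a, b), r in self.comparisons.items()
            },
            "backcalc_summary": self.backcalc_summary(),
        }


def _features(curves, fits, feature_set: str) -> CurveFeatures:
    cols = {
        "slope_intercept": lambda f: (f.slope, f.intercept),
        "slope": lambda f: (f.slope,),
        "intercept": lambda f: (f.intercept,),
    }[feature_set]
    return CurveFeatures(
        curve_ids=tuple(c.curve_id for c in curves),
        matrix=np.array([cols(fits[c.curve_id]) for c in curves]),
        feature_set=feature_set,
    )


def _cluster_mean_responses(cluster_curves: list[CalibrationCurve]) -> dict[float, float]:
    """Per-level mean response across a cluster's curves."""
    acc: dict[float, list[float]] = {}
    for c in cluster_curves:
        for p in c.points:
            acc.setdefault(p.level, []).append(p.response)
    return {lv: float(np.mean(v)) for lv, v in acc.items()}


def run_workflow(
    curves: list[CalibrationCurve], config: WorkflowConfig | None = None
) -> WorkflowReport:
    """Run the full decision pipeline on a set of calibration curves."""
    cfg = config or WorkflowConfig()
    if len(curves) < 2:
        raise DegenerateInputError("workflow needs >=2 curves")
    fits = {c.curve_id: fit_ols(c) for c in curves}
    log.info("stage fit: %d curves fitted", len(curves))

    global_eq = extra_ss_f_test(curves, alpha=cfg.alpha)
    log.info(
        "stage global-equivalence: F=%.4g p=%.4g -> %s",
        global_eq.f_statistic,
        global_eq.p_value,
        "equivalent" if global_eq.equivalent else "not equivalent",
    )
    if global_eq.equivalent:
        return WorkflowReport(
            curves=tuple(curves),
            fits=fits,
            global_equivalence=global_eq,
            clustering=None,
            alt_clusterings={},
            clusters=(
                ClusterSummary(
                    label=0,
                    curve_ids=tuple(c.curve_id for c in curves),
                    equivalence=global_eq,
                    consensus=global_eq.pooled_fit,
                    equivalent=True,
                ),
            ),
            comparisons={},
            backcalc=_backcalc_matrix(curves, {0: global_eq.pooled_fit}, {c.curve_id: 0 for c in curves}),
            recommendation="single_consensus",
            config=cfg,
        )

    m = len(curves)
    ks = range(cfg.k_min, min(cfg.k_max, m - 1) + 1)
    main = select_k(_features(curves, fits, cfg.feature_set), ks)
    alts = {
        fs: select_k(_features(curves, fits, fs), ks)
        for fs in FEATURE_SETS
        if fs != cfg.feature_set
    }
    log.info(
        "stage clustering (%s): chose k=%d (silhouette %.4f)",
        cfg.feature_set,
        main.chosen_k,
        main.silhouette_by_k[main.chosen_k],
    )

    cluster_of = {c.curve_id: int(lab) for c, lab in zip(curves, main.labels)}
    summaries: list[ClusterSummary] = []
    consensus_fits: dict[int, LinearFit] = {}
    for lab in sorted(set(cluster_of.values())):
        members = [c for c in curves if cluster_of[c.curve_id] == lab]
        if len(members) == 1:
            cons = fits[members[0].curve_id]
            summaries.append(
                ClusterSummary(
                    label=lab,
                    curve_ids=(members[0].curve_id,),
                    equivalence=None,
                    consensus=cons,
                    equivalent=True,
                )
            )
            consensus_fits[lab] = cons
            continue
        eq = extra_ss_f_test(members, alpha=cfg.alpha)
        cons = eq.pooled_fit if eq.equivalent else None
        if not eq.equivalent:
            log.warning(
                "cluster %d not internally equivalent (p=%.4g); excluded from consensus",
                lab,
                eq.p_value,
            )
        summaries.append(
            ClusterSummary(
                label=lab,
                curve_ids=tuple(c.curve_id for c in members),
                equivalence=eq,
                consensus=cons,
                equivalent=eq.equivalent,
            )
        )
        if cons is not None:
            consensus_fits[lab] = cons

    # clusters failing internal equivalence are excluded from consensus
    # fitting but still compared: the comparison runs on observed per-level
    # mean responses, not on the consensus lines
    comparisons: dict[tuple[int, int], MethodComparisonResult] = {}
    labs = sorted(set(cluster_of.values()))
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            mean_a = _cluster_mean_responses([c for c in curves if cluster_of[c.curve_id] == a])
            mean_b = _cluster_mean_responses([c for c in curves if cluster_of[c.curve_id] == b])
            shared = sorted(set(mean_a) & set(mean_b))
            if len(shared) < 3:
                log.warning("clusters %d/%d share <3 levels; comparison skipped", a, b)
                continue
            data = PairedResponses(
                x=np.array([mean_a[lv] for lv in shared]),
                y=np.array([mean_b[lv] for lv in shared]),
            )
            comparisons[(a, b)] = compare_methods(data, lam=cfg.lam)
            log.info(
                "stage comparison %d vs %d: Deming slope %.4f, PB slope %.4f",
                a,
                b,
                comparisons[(a, b)].deming.slope,
                comparisons[(a, b)].passing_bablok.slope,
            )

    backcalc = _backcalc_matrix(curves, consensus_fits, cluster_of)
    any_equiv = any(s.equivalent for s in summaries)
    recommendation = "per_cluster_consensus" if any_equiv else "no_consensus"
    log.info("stage recommendation: %s", recommendation)
    return WorkflowReport(
        curves=tuple(curves),
        fits=fits,
        global_equivalence=global_eq,
        clustering=main,
        alt_clusterings=alts,
        clusters=tuple(summaries),
        comparisons=comparisons,
        backcalc=backcalc,
        recommendation=recommendation,
        config=cfg,
    )


def _backcalc_matrix(
    curves: list[CalibrationCurve],
    consensus_fits: dict[int, LinearFit],
    cluster_of: dict[str, int],
) -> pd.DataFrame:
    """|%RE| of every point of every curve against every consensus curve."""
    rows = []
    for c in curves:
        for lab, fit in consensus_fits.items():
            for p in c.points:
                rows.append(
                    {
                        "curve_id": c.curve_id,
                        "group": c.group,
                        "cluster": cluster_of[c.curve_id],
                        "consensus_cluster": lab,
                        "own": cluster_of[c.curve_id] == lab,
                        "level": p.level,
                        "pct_error": back_calc_error(fit, p.response, p.level),
                    }
                )
    return pd.DataFrame(rows)
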