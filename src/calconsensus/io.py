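"""Reading calibration CSVs and writing structured reports.

The on-disk calibration format is a plain UTF-8 CSV with a header row and
columns ``curve_id, group, level, response, replicate`` (decimal point,
levels in ng g^-1, responses as analyte/IS area ratios).  Reports are
written as one JSON document plus flat per-table CSVs so plots (dendrograms,
Bland-Altman, QQ) can be drawn in any environment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .core import CalibrationCurve, CalibrationPoint
from .errors import ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .workflow import WorkflowReport

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("curve_id", "group", "level", "response", "replicate")


def curves_to_frame(curves: list[CalibrationCurve]) -> pd.DataFrame:
    rows = [
        {
            "curve_id": c.curve_id,
            "group": c.group,
            "level": p.level,
            "response": p.response,
            "replicate": p.replicate,
        }
        for c in curves
        for p in c.points
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_calibration_csv(curves: list[CalibrationCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> list[CalibrationCurve]:
    """Parse a calibration CSV into curves, preserving file order.

    Rows with non-positive levels are dropped with a warning (the blank
    level never enters the regression); non-numeric values and duplicate
    (curve, level, replicate) triples raise :class:`ParseError` with the
    offending line numbers (1-based, counting the header as line 1).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    lines = df.index + 2  # header is line 1
    for col in ("level", "response"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = lines[coerced.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing {col} at line(s) {list(bad[:10])}"
            )
        df[col] = coerced
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df["replicate"].isna().any():
        raise ParseError(
            f"{path}: non-numeric replicate at line(s) "
            f"{list(lines[df['replicate'].isna()][:10])}"
        )
    dup = df.duplicated(subset=["curve_id", "level", "replicate"], keep=False)
    if dup.any():
        raise ParseError(
            f"{path}: duplicate (curve_id, level, replicate) at line(s) "
            f"{list(lines[dup][:10])}"
        )
    nonpos = df["level"] <= 0
    if nonpos.any():
        log.warning(
            "%s: dropping %d row(s) with non-positive level (lines %s)",
            path,
            int(nonpos.sum()),
            list(lines[nonpos][:10]),
        )
        df = df[~nonpos]
    curves: list[CalibrationCurve] = []
    for cid in df["curve_id"].drop_duplicates():
        sub = df[df["curve_id"] == cid]
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ParseError(f"{path}: curve {cid!r} has conflicting groups {list(groups)}")
        points = tuple(
            CalibrationPoint(
                level=float(r.level), response=float(r.response), replicate=int(r.replicate)
            )
            for r in sub.itertuples()
        )
        curves.append(CalibrationCurve(curve_id=str(cid), group=str(groups[0]), points=points))
    log.info("%s: read %d rows into %d curves", path, len(df), len(curves))
    return curves


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: "WorkflowReport", out_dir: str | Path) -> list[Path]:
    """Serialise a workflow report to ``report.json`` plus per-table CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    json_path.write_text(json.dumps(_jsonable(report.to_dict()), indent=2))
    written.append(json_path)

    fits_path = out / "fits.csv"
    report.fits_table().to_csv(fits_path, index=False)
    written.append(fits_path)

    if report.backcalc is not None and len(report.backcalc):
        p = out / "backcalc.csv"
        report.backcalc.to_csv(p, index=False)
        written.append(p)

    if report.clustering is not None:
        p = out / "merges.csv"
        pd.DataFrame(
            [
                {"step": s.step, "left": s.left, "right": s.right, "height": s.height}
                for s in report.clustering.merge_history
            ]
        ).to_csv(p, index=False)
        written.append(p)

    for (a, b), cmp_res in report.comparisons.items():
        p = out / f"comparison_{a}_vs_{b}.csv"
        ba = cmp_res.bland_altman
        pd.DataFrame(
            {
                "x": cmp_res.data.x,
                "y": cmp_res.data.y,
                "difference": ba.differences,
                "mean": ba.means,
            }
        ).to_csv(p, index=False)
        written.append(p)
    log.info("wrote %d report file(s) to %s", len(written), out)
    return written
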