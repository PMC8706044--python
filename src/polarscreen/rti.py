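"""Retention-time-index calibration: mapping RPLC retention to LogD(pH 7).

A target analysis of a reference mixture of compounds with stable,
known LogD gives (RT, LogD) pairs in the RPLC regime; an ordinary
least-squares line through them converts any feature RT into a predicted
LogD, which is compared with database LogD values to form the RTI
sub-score.  HILIC-eluting features are not calibrated (their annotation
uses the LogD sign filter only), so only standards at or beyond the
15-min column switch enter the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import pandas as pd
from scipy import stats

from .records import COLUMN_SWITCH_RT


@dataclass(frozen=True)
class CalibrationStandard:
    name: str
    rt: float
    logd_ph7: float


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line LogD = slope * rt + intercept over the RPLC standards."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    rt_range: tuple[float, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        d["rt_range"] = tuple(d["rt_range"])
        return cls(**d)


class LogDPrediction(NamedTuple):
    logd: float
    extrapolated: bool


def standards_from_frame(df: pd.DataFrame) -> list[CalibrationStandard]:
    """Read standards from a ``name, rt_min, logd_ph7`` table."""
    return [CalibrationStandard(str(r.name_), float(r.rt_min), float(r.logd_ph7))
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    min_rt: float = COLUMN_SWITCH_RT,
) -> CalibrationModel:
    """Least-squares RT-LogD line through the RPLC-regime standards.

    Standards eluting before ``min_rt`` are excluded.  The fit refuses to
    return a non-increasing line (slope <= 0): on this column order,
    later RPLC elution always means higher LogD, so a non-positive slope
    indicates corrupt standards rather than usable calibration.
    """
    pts = [(s.rt, s.logd_ph7) for s in standards if s.rt >= min_rt]
    if len(pts) < 3:
        raise ValueError(f"need >=3 RPLC-regime standards, got {len(pts)}")
    rts = [p[0] for p in pts]
    logds = [p[1] for p in pts]
    if max(rts) == min(rts):
        raise ValueError("degenerate calibration: all standards share one RT")
    res = stats.linregress(rts, logds)
    if res.slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {res.slope:.4g}")
    fitted = [res.slope * rt + res.intercept for rt in rts]
    dof = max(len(pts) - 2, 1)
    residual_sd = (sum((y - f) ** 2 for y, f in zip(logds, fitted)) / dof) ** 0.5
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        residual_sd=float(residual_sd),
        n_points=len(pts),
        rt_range=(float(min(rts)), float(max(rts))),
    )


def predict_logd(model: CalibrationModel, rt: float) -> LogDPrediction:
    """Predicted LogD at an RT; flagged when outside the fitted RT range.

    No extrapolation guard is applied beyond the flag -- HILIC-regime RTs
    in particular yield a prediction that should not be trusted and is
    marked ``extrapolated``.
    """
    logd = model.slope * rt + model.intercept
    lo, hi = model.rt_range
    return LogDPrediction(float(logd), not (lo <= rt <= hi))


def rti_subscore(predicted_logd: float, database_logd: float, scale: float = 2.0) -> float:
    """Bounded linear agreement score between predicted and database LogD.

    1 at perfect agreement, declining linearly to 0 at a discrepancy of
    ``scale`` LogD units and clamped there.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return max(0.0, 1.0 - abs(predicted_logd - database_logd) / scale)
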