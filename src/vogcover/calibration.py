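"""Model-eye linear calibration and degree/prism-diopter conversion.

The VOG device's raw angle readout is related to the true eyeball
rotation by an affine map, established once by filming a model eye at
known rotations.  Ordinary least squares of the true angle on the VOG
reading gives the calibration model

    true_deg = slope * vog_deg + intercept

which is then applied to subject measurements.  Calibrated angles are
converted to prism diopters with PD = tan(theta) * 100 (1 PD = 1 cm of
displacement at 1 m).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError
from .traces import GazeTrace

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "deg_to_pd",
    "pd_to_deg",
    "dwell_values",
    "identity_model",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine device calibration with its goodness-of-fit summary."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise InputError("a calibration model needs n_points >= 2")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise InputError("r_squared must lie in [0, 1]")
        if abs(self.pearson_r) > 1 + 1e-9:
            raise InputError("|pearson_r| must be <= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        try:
            return cls(slope=float(d["slope"]), intercept=float(d["intercept"]),
                       r_squared=float(d["r_squared"]),
                       pearson_r=float(d["pearson_r"]),
                       n_points=int(d["n_points"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed calibration model: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        try:
            with open(path) as fh:
                return cls.from_dict(json.load(fh))
        except OSError as exc:
            raise InputError(f"cannot read calibration model {path}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise InputError(f"{path} is not valid JSON: {exc}") from exc


def identity_model() -> CalibrationModel:
    """Calibration that passes angles through unchanged."""
    return CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0,
                            pearson_r=1.0, n_points=2)


def fit_calibration(vog_deg, true_deg) -> CalibrationModel:
    """OLS fit of true rotation on the VOG readout.

    The regression direction matches how the model is used: predict the
    true eyeball rotation from the device's reading.
    """
    x = np.asarray(vog_deg, dtype=float)
    y = np.asarray(true_deg, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("vog_deg and true_deg must be 1-D and equal-length")
    if x.size < 2:
        raise InputError("calibration needs at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("calibration inputs must be finite")
    if np.ptp(x) < 1e-12:
        raise ComputationError("degenerate calibration: all VOG readings identical")
    res = stats.linregress(x, y)
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            pearson_r=float(res.rvalue), n_points=int(x.size))


def apply_calibration(model: CalibrationModel, vog_deg):
    """Convert a raw VOG angle (degrees) to a calibrated rotation angle."""
    vog = np.asarray(vog_deg, dtype=float)
    if not np.all(np.isfinite(vog)):
        raise InputError("vog_deg must be finite")
    out = model.slope * vog + model.intercept
    return float(out) if np.isscalar(vog_deg) else out


def deg_to_pd(angle_deg):
    """Degrees to prism diopters: PD = tan(angle) * 100; |angle| < 90°."""
    a = np.asarray(angle_deg, dtype=float)
    if np.any(np.abs(a) >= 90.0):
        raise InputError("deg_to_pd requires |angle| < 90 degrees")
    out = np.tan(np.radians(a)) * 100.0
    return float(out) if np.isscalar(angle_deg) else out


def pd_to_deg(pd):
    """Prism diopters to degrees: the exact inverse of :func:`deg_to_pd`."""
    p = np.asarray(pd, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InputError("pd must be finite")
    out = np.degrees(np.arctan(p / 100.0))
    return float(out) if np.isscalar(pd) else out


def dwell_values(trace: GazeTrace, dwell_table: pd.DataFrame,
                 trim_s: float = 0.5, min_confidence: float = 0.5) -> np.ndarray:
    """Median VOG angle within each model-eye dwell segment.

    ``trim_s`` is cut from each end of the dwell so settling frames at
    the rotation boundaries never contaminate the median.
    """
    values = []
    for _, row in dwell_table.iterrows():
        start = float(row["start_s"]) + trim_s
        end = float(row["end_s"]) - trim_s
        if end <= start:
            start, end = float(row["start_s"]), float(row["end_s"])
        sub = trace.window(start, end)
        mask = sub.valid_mask(min_confidence)
        if not mask.any():
            raise ComputationError(
                f"dwell {row['dwell_index']} has no valid samples")
        values.append(float(np.median(sub.x_deg[mask])))
    return np.asarray(values)
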