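"""Time-indexed angular eye-position traces and their CSV serialization.

A :class:`GazeTrace` holds one eye's horizontal/vertical gaze angles in
degrees, sampled at a fixed rate, with a per-sample confidence in [0, 1].
Samples with confidence 0 (blinks, occluder dropouts, failed pupil fits)
may carry NaN angles; every consumer is expected to filter on confidence.

CSV layout (one file may hold both eyes)::

    time_s,eye,x_deg,y_deg,confidence
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

EYES = ("left", "right")

TRACE_COLUMNS = ["time_s", "eye", "x_deg", "y_deg", "confidence"]


@dataclass
class GazeTrace:
    """Angular position of one eye over time.

    Angles are in degrees, positive temporal-ward for the given eye.
    Times must be strictly increasing; confidence lies in [0, 1].
    """

    eye: str
    time_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    confidence: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        if self.eye not in EYES:
            raise InputError(f"eye must be one of {EYES}, got {self.eye!r}")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = self.time_s.size
        for name in ("x_deg", "y_deg", "confidence"):
            if getattr(self, name).size != n:
                raise InputError(f"{name} length does not match time_s")
        if n and np.any(np.diff(self.time_s) <= 0):
            raise InputError("time_s must be strictly increasing")
        if n and (np.nanmin(self.confidence) < 0 or np.nanmax(self.confidence) > 1):
            raise InputError("confidence must lie in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise InputError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.time_s.size

    def valid_mask(self, min_confidence: float = 0.5) -> np.ndarray:
        """Samples that are trustworthy: confident and finite."""
        return (self.confidence >= min_confidence) & np.isfinite(self.x_deg)

    def window(self, start_s: float, end_s: float) -> "GazeTrace":
        """Sub-trace with start_s <= t < end_s."""
        m = (self.time_s >= start_s) & (self.time_s < end_s)
        return GazeTrace(
            eye=self.eye,
            time_s=self.time_s[m],
            x_deg=self.x_deg[m],
            y_deg=self.y_deg[m],
            confidence=self.confidence[m],
            sample_rate_hz=self.sample_rate_hz,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "eye": self.eye,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "confidence": self.confidence,
            }
        )


def write_trace_csv(path, traces) -> None:
    """Write one or several GazeTraces to a single CSV file."""
    if isinstance(traces, GazeTrace):
        traces = [traces]
    df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path, sample_rate_hz: float | None = None) -> dict[str, GazeTrace]:
    """Read a trace CSV; returns a dict keyed by eye.

    If ``sample_rate_hz`` is omitted it is inferred from the median time
    step of the first eye present.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read trace CSV {path}: {exc}") from exc
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trace CSV {path} is missing columns {sorted(missing)}")
    out: dict[str, GazeTrace] = {}
    for eye, sub in df.groupby("eye", sort=True):
        sub = sub.sort_values("time_s")
        rate = sample_rate_hz
        if rate is None:
            dt = np.median(np.diff(sub["time_s"].to_numpy()))
            if not np.isfinite(dt) or dt <= 0:
                raise InputError(f"cannot infer sample rate for eye {eye!r}")
            rate = 1.0 / dt
        out[str(eye)] = GazeTrace(
            eye=str(eye),
            time_s=sub["time_s"].to_numpy(),
            x_deg=sub["x_deg"].to_numpy(),
            y_deg=sub["y_deg"].to_numpy(),
            confidence=sub["confidence"].to_numpy(),
            sample_rate_hz=float(rate),
        )
    if not out:
        raise InputError(f"trace CSV {path} contains no samples")
    return out
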