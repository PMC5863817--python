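"""Per-alternation deviation extraction from gaze traces.

During the alternate-cover exam the covered eye drifts to its
dissociated (deviated) position; when the occluder swaps, that eye makes
a re-fixation saccade back to the target.  The deviation for one
alternation cycle is the step height between the eye's position while it
was covered and its position after re-fixation — measured here as the
absolute difference of two window medians bracketing the transition.

Windows (configurable): the *pre* window is the last second of the
covered interval; the *settle* window is 0.3-1.5 s after the uncover,
skipping the saccade ramp.  Medians over confidence-filtered samples
make the estimate robust to blinks and tracker dropouts.  Only the
horizontal channel feeds the headline measurement (comitant horizontal
exotropia); the vertical channel is carried through but unused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UnmeasurableSessionError
from .synthetic_data import CoverSchedule
from .traces import GazeTrace

__all__ = [
    "GazeTrace",
    "WindowConfig",
    "CycleDeviation",
    "SessionMeasurement",
    "extract_cycle_deviations",
    "aggregate_session",
    "select_test_value",
]

AGGREGATION_METHODS = ("median", "mean", "first")


@dataclass(frozen=True)
class WindowConfig:
    """Measurement windows around each cover-to-uncover transition."""

    pre_window_s: float = 1.0
    settle_start_s: float = 0.3
    settle_end_s: float = 1.5
    min_confidence: float = 0.5
    min_valid_samples: int = 10

    def __post_init__(self):
        if self.pre_window_s <= 0:
            raise InputError("pre_window_s must be positive")
        if not (0 <= self.settle_start_s < self.settle_end_s):
            raise InputError("settle window must satisfy 0 <= start < end")
        if self.min_valid_samples < 1:
            raise InputError("min_valid_samples must be >= 1")


@dataclass(frozen=True)
class CycleDeviation:
    """One alternation cycle's measured deviation (unsigned, degrees)."""

    cycle_index: int
    eye: str
    deviation_deg: float
    pre_window_mean_deg: float
    post_window_mean_deg: float
    n_valid_samples: int
    usable: bool


@dataclass
class SessionMeasurement:
    """Aggregated deviation of one alternate-cover session."""

    deviation_deg: float
    per_cycle: list[CycleDeviation]
    n_usable_cycles: int
    method: str

    def to_dict(self) -> dict:
        return {
            "deviation_deg": self.deviation_deg,
            "method": self.method,
            "n_usable_cycles": self.n_usable_cycles,
            "per_cycle": [
                {
                    "cycle_index": c.cycle_index,
                    "eye": c.eye,
                    "deviation_deg": c.deviation_deg,
                    "pre_window_mean_deg": c.pre_window_mean_deg,
                    "post_window_mean_deg": c.post_window_mean_deg,
                    "n_valid_samples": c.n_valid_samples,
                    "usable": c.usable,
                }
                for c in self.per_cycle
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _window_median(trace: GazeTrace, start: float, end: float,
                   min_confidence: float) -> tuple[float, int]:
    sub = trace.window(start, end)
    mask = sub.valid_mask(min_confidence)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.median(sub.x_deg[mask])), n


def extract_cycle_deviations(trace_left: GazeTrace, trace_right: GazeTrace,
                             schedule: CoverSchedule,
                             windows: WindowConfig | None = None
                             ) -> list[CycleDeviation]:
    """Measure the re-fixation step at every cover-to-uncover transition.

    For each pair of consecutive schedule intervals where the first
    covers eye E, eye E is newly uncovered at the boundary; its deviation
    is ``|median(pre window) - median(settle window)|`` on the horizontal
    channel.  Transitions with too few valid samples in either window
    yield ``usable=False`` rather than an exception.
    """
    if windows is None:
        windows = WindowConfig()
    traces = {"left": trace_left, "right": trace_right}
    for eye, tr in traces.items():
        if tr.eye != eye:
            raise InputError(f"trace passed as {eye} is labelled {tr.eye!r}")
        if tr.time_s.size and tr.time_s[-1] < schedule.total_duration_s - 1.5:
            raise InputError("trace does not span the cover schedule")

    cycles: list[CycleDeviation] = []
    cycle_index = 0
    intervals = schedule.intervals
    for (start, end, covered), (nstart, nend, _) in zip(intervals, intervals[1:]):
        if covered not in ("left", "right"):
            continue
        trace = traces[covered]
        pre_start = max(start, end - windows.pre_window_s)
        pre, n_pre = _window_median(trace, pre_start, end, windows.min_confidence)
        settle_start = end + windows.settle_start_s
        settle_end = min(end + windows.settle_end_s, nend)
        post, n_post = _window_median(trace, settle_start, settle_end,
                                      windows.min_confidence)
        n_valid = min(n_pre, n_post)
        usable = n_valid >= windows.min_valid_samples
        deviation = abs(pre - post) if usable else float("nan")
        cycles.append(CycleDeviation(
            cycle_index=cycle_index, eye=covered, deviation_deg=deviation,
            pre_window_mean_deg=pre, post_window_mean_deg=post,
            n_valid_samples=n_valid, usable=usable))
        cycle_index += 1
    return cycles


def aggregate_session(cycles: list[CycleDeviation],
                      method: str = "median") -> SessionMeasurement:
    """Collapse per-cycle deviations to one session value.

    The default is the median of the usable cycles, which tolerates one
    or two corrupted alternations; ``mean`` and ``first`` are provided
    for comparison with protocols that specify them.
    """
    if method not in AGGREGATION_METHODS:
        raise InputError(f"method must be one of {AGGREGATION_METHODS}")
    usable = [c for c in cycles if c.usable]
    if not usable:
        raise UnmeasurableSessionError(
            "no usable alternation cycle; session cannot be measured")
    values = np.array([c.deviation_deg for c in usable])
    if method == "median":
        value = float(np.median(values))
    elif method == "mean":
        value = float(np.mean(values))
    else:
        value = float(values[0])
    return SessionMeasurement(deviation_deg=value, per_cycle=list(cycles),
                              n_usable_cycles=len(usable), method=method)


def select_test_value(session_values, rule: str = "first") -> float:
    """Pick the reported value from repeated sessions (test-retest runs).

    ``first`` keeps the first session's value; ``mean`` averages all of
    them.  Both selection rules are in routine clinical use.
    """
    values = list(session_values)
    if not values:
        raise InputError("session_values must contain at least one value")
    if rule == "first":
        return float(values[0])
    if rule == "mean":
        return float(np.mean(values))
    raise InputError("rule must be 'first' or 'mean'")
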