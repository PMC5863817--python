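"""Synthetic model-eye and subject sessions with known ground truth.

Two kinds of input are generated, mirroring the physical measurement
protocol of a video-oculography (VOG) alternate-cover exam:

* **Model-eye calibration sessions** — an artificial eyeball (globe
  diameter 26 mm, pupil diameter 5.5 mm) is rotated in 2° steps from 0°
  to 30°, holding each position for at least 5 s while the camera films
  it.  The renderer draws the dark pupil disc on a bright background;
  the pupil-center pixel displacement follows an orthographic camera
  model, ``dx_px = pixels_per_mm * globe_radius_mm * sin(theta)``.  An
  affine device distortion (slope, intercept) is injected so the
  downstream calibration stage has a nontrivial relationship to recover.

* **Subject sessions** — an exotropic subject under the alternate-cover
  protocol: 10 s of binocular viewing, then each eye alternately covered
  for 5 s, repeated 5 times (60 s total at 120 Hz).  The covered eye
  drifts to its dissociated (deviated) position; on uncovering it makes
  a re-fixation saccade back to the target.  The step height of that
  re-fixation is the quantity the pipeline measures.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .traces import GazeTrace

__all__ = [
    "EyeGeometry",
    "SubjectSimParams",
    "CoverSchedule",
    "default_schedule",
    "render_pupil_frame",
    "simulate_model_eye_session",
    "simulate_subject_session",
    "ModelEyeSession",
    "SubjectSession",
]

#: maximum physical rotation supported by the model-eye protocol
MAX_MODEL_EYE_DEG = 30.0

# 8-bit grayscale rendering levels: bright sclera/background, dark pupil
_BACKGROUND_LEVEL = 200.0
_PUPIL_LEVEL = 30.0


@dataclass(frozen=True)
class EyeGeometry:
    """Physical and imaging geometry of the (model) eye.

    The projected pupil must stay inside the frame for rotations up to
    30°, including the affine device distortion margin; the defaults
    leave ample room.
    """

    globe_diameter_mm: float = 26.0
    pupil_diameter_mm: float = 5.5
    pixels_per_mm: float = 10.0
    image_width_px: int = 320
    image_height_px: int = 240

    def __post_init__(self):
        for name in ("globe_diameter_mm", "pupil_diameter_mm", "pixels_per_mm"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise InputError("image dimensions must be positive")
        if self.pupil_diameter_mm >= self.globe_diameter_mm:
            raise InputError("pupil_diameter_mm must be smaller than globe_diameter_mm")
        # pupil disc must fit in-frame at the maximum protocol rotation
        max_dx = self.displacement_px(MAX_MODEL_EYE_DEG)
        if self.resting_center_px[0] + max_dx + self.pupil_radius_px >= self.image_width_px - 1:
            raise InputError("projected pupil leaves the frame at 30 degrees; "
                             "enlarge the image or reduce pixels_per_mm")

    @property
    def globe_radius_mm(self) -> float:
        return self.globe_diameter_mm / 2.0

    @property
    def pupil_radius_px(self) -> float:
        return self.pupil_diameter_mm / 2.0 * self.pixels_per_mm

    @property
    def resting_center_px(self) -> tuple[float, float]:
        """Pupil-center pixel position at 0° (center-of-pixel coordinates)."""
        return ((self.image_width_px - 1) / 2.0, (self.image_height_px - 1) / 2.0)

    def displacement_px(self, angle_deg) -> np.ndarray | float:
        """Horizontal pixel displacement of the pupil center at ``angle_deg``."""
        return self.pixels_per_mm * self.globe_radius_mm * np.sin(np.radians(angle_deg))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EyeGeometry":
        return cls(**d)


@dataclass(frozen=True)
class SubjectSimParams:
    """Parameters of the exotropic subject forward model.

    ``true_deviation_deg`` is the dissociated exodeviation magnitude the
    covered eye drifts to.  ``phoria_noise_sd_deg`` jitters that target
    independently per cover episode (dissociated angle is not perfectly
    repeatable); ``trace_noise_sd_deg`` is additive per-sample tracker
    noise.  Deviations at or above 26.57° (50 prism diopters) are outside
    the method's working range and rejected.
    """

    true_deviation_deg: float = 14.0
    phoria_noise_sd_deg: float = 0.25
    trace_noise_sd_deg: float = 0.2
    blink_rate_hz: float = 0.1
    saccade_duration_s: float = 0.05
    sample_rate_hz: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.true_deviation_deg < 0:
            raise InputError("true_deviation_deg must be non-negative")
        if self.true_deviation_deg >= math.degrees(math.atan(0.5)):  # 50 PD bound
            raise InputError("deviation >= 50 prism diopters (26.57 deg) is out of range")
        if self.sample_rate_hz <= 0:
            raise InputError("sample_rate_hz must be positive")
        for name in ("phoria_noise_sd_deg", "trace_noise_sd_deg", "blink_rate_hz",
                     "saccade_duration_s"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CoverSchedule:
    """Timed occlusion plan: ordered, contiguous (start, end, covered_eye).

    ``covered_eye`` is ``"left"``, ``"right"`` or ``"none"`` (binocular
    viewing).  Intervals partition [0, total_duration_s] exactly and the
    first interval is binocular.
    """

    intervals: tuple[tuple[float, float, str], ...]
    total_duration_s: float

    def __post_init__(self):
        if not self.intervals:
            raise InputError("schedule must contain at least one interval")
        prev_end = 0.0
        for i, (start, end, eye) in enumerate(self.intervals):
            if eye not in ("left", "right", "none"):
                raise InputError(f"covered_eye must be left/right/none, got {eye!r}")
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise InputError("schedule intervals must be contiguous and ordered")
            if end <= start:
                raise InputError("schedule intervals must have positive length")
            prev_end = end
        if not math.isclose(prev_end, self.total_duration_s, abs_tol=1e-9):
            raise InputError("intervals must cover exactly [0, total_duration_s]")

    def __len__(self) -> int:
        return len(self.intervals)

    def covered_eye_at(self, t: float) -> str:
        for start, end, eye in self.intervals:
            if start <= t < end:
                return eye
        return "none"

    def to_dict(self) -> dict:
        return {
            "intervals": [
                {"start_s": s, "end_s": e, "covered_eye": eye}
                for s, e, eye in self.intervals
            ],
            "total_duration_s": self.total_duration_s,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CoverSchedule":
        try:
            intervals = tuple(
                (float(iv["start_s"]), float(iv["end_s"]), str(iv["covered_eye"]))
                for iv in d["intervals"]
            )
            return cls(intervals=intervals, total_duration_s=float(d["total_duration_s"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed schedule: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "CoverSchedule":
        try:
            with open(path) as fh:
                return cls.from_dict(json.load(fh))
        except OSError as exc:
            raise InputError(f"cannot read schedule {path}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise InputError(f"schedule {path} is not valid JSON: {exc}") from exc


def default_schedule(n_cycles: int = 5, binocular_lead_s: float = 10.0,
                     cover_s: float = 5.0, first_covered: str = "left") -> CoverSchedule:
    """Alternate-cover schedule: a binocular lead then n_cycles of L/R covers.

    With the protocol defaults (5 cycles, 10 s lead, 5 s per cover) the
    schedule has 11 intervals and lasts 60 s.  A zero-length binocular
    lead is dropped, so the first cover then starts at t = 0.
    """
    if n_cycles < 1:
        raise InputError("n_cycles must be >= 1")
    if cover_s <= 0:
        raise InputError("cover_s must be positive")
    if binocular_lead_s < 0:
        raise InputError("binocular_lead_s must be non-negative")
    if first_covered not in ("left", "right"):
        raise InputError("first_covered must be 'left' or 'right'")
    other = "right" if first_covered == "left" else "left"
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    if binocular_lead_s > 0:
        intervals.append((0.0, binocular_lead_s, "none"))
        t = binocular_lead_s
    for _ in range(n_cycles):
        for eye in (first_covered, other):
            intervals.append((t, t + cover_s, eye))
            t += cover_s
    return CoverSchedule(intervals=tuple(intervals), total_duration_s=t)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def render_pupil_frame(geometry: EyeGeometry, center_x_px: float, center_y_px: float,
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one 8-bit grayscale frame with an anti-aliased dark pupil disc.

    Anti-aliasing (linear edge coverage over one pixel) is what makes
    subpixel centroid recovery possible downstream.
    """
    h, w = geometry.image_height_px, geometry.image_width_px
    yy = np.arange(h, dtype=float)[:, None]
    xx = np.arange(w, dtype=float)[None, :]
    dist = np.hypot(xx - center_x_px, yy - center_y_px)
    coverage = np.clip(geometry.pupil_radius_px + 0.5 - dist, 0.0, 1.0)
    img = _BACKGROUND_LEVEL + (_PUPIL_LEVEL - _BACKGROUND_LEVEL) * coverage
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class ModelEyeSession:
    """Rendered calibration session plus its ground-truth dwell table.

    ``dwell_table`` columns: dwell_index, true_deg (protractor angle),
    vog_deg (distorted angle actually rendered), start_s, end_s,
    start_frame, end_frame (exclusive).
    """

    frames: np.ndarray  # (n_frames, H, W) uint8
    dwell_table: pd.DataFrame
    frame_rate_hz: float
    geometry: EyeGeometry
    device_slope: float
    device_intercept: float


def simulate_model_eye_session(geometry: EyeGeometry | None = None,
                               angles_deg=None,
                               dwell_s: float = 5.0,
                               device_slope: float = 1.0,
                               device_intercept: float = 0.0,
                               frame_rate_hz: float = 10.0,
                               noise_sd: float = 0.0,
                               seed: int = 0) -> ModelEyeSession:
    """Film a model eye stepped through known rotations.

    The device distortion is affine: a true protractor angle ``theta``
    is displayed (and rendered) by the device as
    ``vog = (theta - device_intercept) / device_slope``, so that
    regressing truth on the measured VOG angle recovers exactly
    (device_slope, device_intercept).

    ``angles_deg`` defaults to 0°..30° in 2° steps (16 dwells).  Each
    dwell must last at least 5 s.  The default frame rate keeps a full
    16-dwell session small; the dwell positions are static, so the
    frame rate does not affect the dwell statistics.
    """
    if geometry is None:
        geometry = EyeGeometry()
    if angles_deg is None:
        angles_deg = np.arange(0.0, 30.0 + 1e-9, 2.0)
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise InputError("angles_deg must be non-empty")
    if np.any(angles < 0) or np.any(angles > MAX_MODEL_EYE_DEG):
        raise InputError("model-eye angles must lie within [0, 30] degrees")
    if dwell_s < 5.0:
        raise InputError("dwell_s must be at least 5 s")
    if device_slope <= 0:
        raise InputError("device_slope must be positive")
    if frame_rate_hz <= 0:
        raise InputError("frame_rate_hz must be positive")

    rng = np.random.default_rng(seed)
    frames_per_dwell = int(round(dwell_s * frame_rate_hz))
    if frames_per_dwell < 1:
        raise InputError("dwell shorter than one frame period")

    vog_angles = (angles - device_intercept) / device_slope
    rest_x, rest_y = geometry.resting_center_px

    frames = np.empty(
        (frames_per_dwell * angles.size, geometry.image_height_px, geometry.image_width_px),
        dtype=np.uint8,
    )
    rows = []
    for i, (true_deg, vog_deg) in enumerate(zip(angles, vog_angles)):
        cx = rest_x + geometry.displacement_px(vog_deg)
        start = i * frames_per_dwell
        if noise_sd > 0:
            for j in range(frames_per_dwell):
                frames[start + j] = render_pupil_frame(geometry, cx, rest_y, noise_sd, rng)
        else:
            frame = render_pupil_frame(geometry, cx, rest_y)
            frames[start:start + frames_per_dwell] = frame
        rows.append(
            {
                "dwell_index": i,
                "true_deg": true_deg,
                "vog_deg": vog_deg,
                "start_s": start / frame_rate_hz,
                "end_s": (start + frames_per_dwell) / frame_rate_hz,
                "start_frame": start,
                "end_frame": start + frames_per_dwell,
            }
        )
    return ModelEyeSession(
        frames=frames,
        dwell_table=pd.DataFrame(rows),
        frame_rate_hz=frame_rate_hz,
        geometry=geometry,
        device_slope=device_slope,
        device_intercept=device_intercept,
    )


# ---------------------------------------------------------------------------
# subject forward model
# ---------------------------------------------------------------------------

@dataclass
class SubjectSession:
    """Simulated alternate-cover session for one exotropic subject."""

    trace_left: GazeTrace
    trace_right: GazeTrace
    schedule: CoverSchedule
    params: SubjectSimParams
    ground_truth: dict


def _eye_position_knots(schedule: CoverSchedule, eye: str, deviation: float,
                        phoria_offsets: dict[int, float],
                        saccade_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear knot points (t, x) for one eye.

    The eye sits at 0° while viewing/fixating, and at
    ``deviation + phoria_offset`` while covered; every state change is a
    linear ramp of length ``saccade_s`` starting at the interval onset.
    """
    times = [0.0]
    pos = [0.0]
    current = 0.0
    for idx, (start, end, covered) in enumerate(schedule.intervals):
        target = deviation + phoria_offsets.get(idx, 0.0) if covered == eye else 0.0
        if start > 0.0 and target != current:
            ramp = min(saccade_s, end - start)
            times.extend([start, start + ramp])
            pos.extend([current, target])
            current = target
    times.append(schedule.total_duration_s)
    pos.append(current)
    return np.asarray(times), np.asarray(pos)


def simulate_subject_session(params: SubjectSimParams,
                             schedule: CoverSchedule | None = None,
                             covered_eye_visible: bool = True) -> SubjectSession:
    """Generate the left/right gaze traces of an alternate-cover exam.

    The covered eye drifts temporal-ward to the dissociated exodeviated
    angle (positive in each eye's own temporal-positive convention); the
    newly uncovered eye re-fixates to 0° with a linear saccade ramp.
    Additive Gaussian tracker noise and blink gaps (confidence 0, NaN
    position, 100-300 ms) complete the forward model.  With
    ``covered_eye_visible=False`` the covered eye's samples are blanked
    instead, emulating an opaque occluder.
    """
    if schedule is None:
        schedule = default_schedule()
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    n = int(round(schedule.total_duration_s * fs))
    t = np.arange(n) / fs

    # one independent dissociated-angle jitter per covered episode
    phoria_offsets: dict[int, float] = {
        idx: (rng.normal(0.0, params.phoria_noise_sd_deg)
              if params.phoria_noise_sd_deg > 0 else 0.0)
        for idx, (_, _, covered) in enumerate(schedule.intervals)
        if covered in ("left", "right")
    }

    traces = {}
    blink_log: dict[str, list[tuple[float, float]]] = {}
    for eye in ("left", "right"):
        kt, kx = _eye_position_knots(schedule, eye, params.true_deviation_deg,
                                     phoria_offsets, params.saccade_duration_s)
        x = np.interp(t, kt, kx)
        y = np.zeros_like(x)
        if params.trace_noise_sd_deg > 0:
            x = x + rng.normal(0.0, params.trace_noise_sd_deg, size=n)
            y = y + rng.normal(0.0, params.trace_noise_sd_deg, size=n)
        conf = np.ones(n)

        blinks = []
        if params.blink_rate_hz > 0:
            n_blinks = rng.poisson(params.blink_rate_hz * schedule.total_duration_s)
            starts = np.sort(rng.uniform(0.0, schedule.total_duration_s, size=n_blinks))
            durations = rng.uniform(0.1, 0.3, size=n_blinks)
            for b0, dur in zip(starts, durations):
                m = (t >= b0) & (t < b0 + dur)
                conf[m] = 0.0
                x[m] = np.nan
                y[m] = np.nan
                blinks.append((float(b0), float(min(b0 + dur, schedule.total_duration_s))))
        blink_log[eye] = blinks

        if not covered_eye_visible:
            for start, end, covered in schedule.intervals:
                if covered == eye:
                    m = (t >= start) & (t < end)
                    conf[m] = 0.0
                    x[m] = np.nan
                    y[m] = np.nan

        traces[eye] = GazeTrace(eye=eye, time_s=t, x_deg=x, y_deg=y,
                                confidence=conf, sample_rate_hz=fs)

    ground_truth = {
        "true_deviation_deg": params.true_deviation_deg,
        "phoria_offsets_deg": {str(k): float(v) for k, v in phoria_offsets.items()},
        "transition_times_s": [float(iv[1]) for iv in schedule.intervals[:-1]],
        "blinks_s": blink_log,
        "seed": params.seed,
    }
    return SubjectSession(trace_left=traces["left"], trace_right=traces["right"],
                          schedule=schedule, params=params, ground_truth=ground_truth)
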