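"""Dynamic amino-acid PET kinetics.

Extracts the static and dynamic uptake metrics used to grade malignant
brain lesions from dynamic PET: standardized uptake value (SUV) and
tumor-to-brain ratio (TBR) means and maxima over the late static window,
the late-window linear slope and intercept, and the time to peak (TTP) of
the dynamic uptake curve.

Conventions
-----------
* Each dynamic frame is timestamped at its midpoint, ``(start + end) / 2``.
* The late analysis window defaults to 20-40 min post-injection
  (``[1200, 2400]`` s), endpoints inclusive.
* Slopes are reported per *hour*; the intercept is the ordinary
  least-squares line extrapolated to ``t = 0`` (injection time), not to
  the window start.  Reported intercept-based cutoffs depend on this
  convention.
* TTP is the midpoint time of the global-maximum frame of the raw
  (unsmoothed) SUV curve; ties resolve to the earliest frame.
* ``TBR_max`` is lesion ``SUV_max`` over the *mean* reference uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LATE_WINDOW_S",
    "FrameSchedule",
    "TimeActivityCurve",
    "PetMetrics",
    "compute_suv",
    "extract_tac",
    "tbr_curve",
    "fit_linear_window",
    "time_to_peak",
    "static_metrics",
    "pet_metrics",
]

#: Default late static/dynamic analysis window, seconds post-injection.
LATE_WINDOW_S: tuple[float, float] = (1200.0, 2400.0)


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of a dynamic acquisition: per-frame start and end times in seconds."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape:
            raise ValueError("starts and ends must be 1-D arrays of equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(ends <= starts):
            raise ValueError("every frame must have end > start")
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError("frames must be ordered and non-overlapping")

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of frames whose midpoint lies in ``window`` (inclusive)."""
        lo, hi = window
        mid = self.midpoints
        return (mid >= lo) & (mid <= hi)

    @classmethod
    def from_frame_list(cls, frames: Sequence[tuple[float, float]]) -> "FrameSchedule":
        arr = np.asarray(frames, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def default_dynamic(cls, scan_end_s: float = 2400.0) -> "FrameSchedule":
        """Default dynamic binning: 4 x 60 s then 12 x 180 s over 0-40 min."""
        durations = [60.0] * 4 + [180.0] * 12
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        ends = np.cumsum(durations)
        sched = cls(starts, ends)
        if not np.isclose(sched.ends[-1], scan_end_s):
            raise ValueError("default binning spans 0-2400 s only")
        return sched


@dataclass
class TimeActivityCurve:
    """Per-frame ROI mean values over a dynamic scan.

    ``unit`` is one of ``"kBq/mL"``, ``"SUV"`` or ``"TBR"``.
    """

    schedule: FrameSchedule
    values: np.ndarray
    unit: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"curve has {self.values.size} values for "
                f"{self.schedule.n_frames} frames"
            )

    @property
    def times_s(self) -> np.ndarray:
        return self.schedule.midpoints

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.values * factor, self.unit)


@dataclass
class PetMetrics:
    """The nine dynamic-PET lesion metrics (SUV and TBR statics + kinetics)."""

    suv_mean: float
    suv_max: float
    suv_slope: float  # SUV / h over the late window
    suv_intercept: float  # SUV at t = 0
    tbr_mean: float
    tbr_max: float
    tbr_slope: float  # TBR / h
    tbr_intercept: float
    ttp_s: float  # seconds post-injection

    def to_dict(self) -> dict[str, float]:
        return {
            "suv_mean": self.suv_mean,
            "suv_max": self.suv_max,
            "suv_slope": self.suv_slope,
            "suv_intercept": self.suv_intercept,
            "tbr_mean": self.tbr_mean,
            "tbr_max": self.tbr_max,
            "tbr_slope": self.tbr_slope,
            "tbr_intercept": self.tbr_intercept,
            "ttp_s": self.ttp_s,
        }


def compute_suv(
    concentration_kbq_ml: float | np.ndarray,
    injected_dose_mbq: float,
    body_weight_kg: float,
) -> float | np.ndarray:
    """Body-weight standardized uptake value.

    ``SUV = C / (dose / weight)`` with tissue density taken as 1 g/mL, so
    a concentration of 10 kBq/mL with 500 MBq injected into 70 kg gives
    ``10 / (500000 kBq / 70000 mL) = 1.4``.
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    conc = np.asarray(concentration_kbq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    suv = conc * body_weight_kg / injected_dose_mbq
    return float(suv) if suv.ndim == 0 else suv


def extract_tac(
    image: np.ndarray,
    mask: np.ndarray,
    schedule: FrameSchedule,
    unit: str = "SUV",
) -> TimeActivityCurve:
    """ROI-mean time-activity curve from a 4-D dynamic image.

    ``image`` is indexed ``(x, y, z, frame)``; ``mask`` is a boolean 3-D
    volume selecting the ROI. The curve value of each frame is the
    arithmetic mean over masked voxels.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.ndim != 4:
        raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
    if mask.shape != image.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image grid {image.shape[:3]}"
        )
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if image.shape[3] != schedule.n_frames:
        raise ValueError("number of frames differs between image and schedule")
    values = image[mask, :].mean(axis=0)
    return TimeActivityCurve(schedule, values, unit)


def _check_same_schedule(a: TimeActivityCurve, b: TimeActivityCurve) -> None:
    if not (
        np.array_equal(a.schedule.starts, b.schedule.starts)
        and np.array_equal(a.schedule.ends, b.schedule.ends)
    ):
        raise ValueError("lesion and reference curves must share one frame schedule")


def tbr_curve(
    lesion: TimeActivityCurve, reference: TimeActivityCurve
) -> TimeActivityCurve:
    """Frame-wise tumor-to-brain ratio: lesion normalized by the contralateral
    reference ROI at every frame."""
    _check_same_schedule(lesion, reference)
    if np.any(reference.values <= 0):
        raise ValueError("reference curve must be strictly positive")
    return TimeActivityCurve(
        lesion.schedule, lesion.values / reference.values, unit="TBR"
    )


def fit_linear_window(
    curve: TimeActivityCurve,
    window: tuple[float, float] = LATE_WINDOW_S,
) -> tuple[float, float]:
    """Late-window linear kinetics: OLS of curve value against frame-midpoint
    time in hours.

    Returns ``(slope, intercept)`` with slope in curve units per hour and
    the intercept extrapolated to ``t = 0``.
    """
    mask = curve.schedule.in_window(window)
    if mask.sum() < 2:
        raise ValueError(
            f"need at least 2 frames with midpoints inside {window}, "
            f"found {int(mask.sum())}"
        )
    t_h = curve.times_s[mask] / 3600.0
    y = curve.values[mask]
    if np.ptp(t_h) == 0:
        raise ValueError("degenerate window: identical frame timestamps")
    slope, intercept = np.polyfit(t_h, y, 1)
    return float(slope), float(intercept)


def time_to_peak(curve: TimeActivityCurve) -> float:
    """Midpoint time (s) of the global-maximum frame; ties break earliest."""
    if curve.values.size == 0:
        raise ValueError("empty curve")
    idx = int(np.argmax(curve.values))  # argmax returns the first maximum
    return float(curve.times_s[idx])


def static_metrics(
    lesion_values: np.ndarray, reference_mean: float
) -> tuple[float, float, float, float]:
    """Static-image lesion metrics from time-averaged late-window uptake.

    Returns ``(suv_mean, suv_max, tbr_mean, tbr_max)`` where both TBR
    variants are normalized by the scalar reference mean.
    """
    lesion_values = np.asarray(lesion_values, dtype=float)
    if lesion_values.size == 0:
        raise ValueError("lesion voxel set is empty")
    if reference_mean <= 0:
        raise ValueError("reference mean must be strictly positive")
    suv_mean = float(lesion_values.mean())
    suv_max = float(lesion_values.max())
    return suv_mean, suv_max, suv_mean / reference_mean, suv_max / reference_mean


def pet_metrics(
    lesion: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: tuple[float, float] = LATE_WINDOW_S,
) -> PetMetrics:
    """All nine lesion metrics from one lesion/reference SUV curve pair.

    SUV statics are the mean/max of the lesion curve over the late window;
    TBR statics divide them by the window-mean reference uptake; slopes and
    intercepts come from OLS fits of the SUV and frame-wise TBR curves; TTP
    is taken on the raw lesion SUV curve over the full scan.
    """
    _check_same_schedule(lesion, reference)
    mask = lesion.schedule.in_window(window)
    if not mask.any():
        raise ValueError("no frames inside the static analysis window")
    suv_mean, suv_max, tbr_mean, tbr_max = static_metrics(
        lesion.values[mask], float(reference.values[mask].mean())
    )
    suv_slope, suv_intercept = fit_linear_window(lesion, window)
    tbr = tbr_curve(lesion, reference)
    tbr_slope, tbr_intercept = fit_linear_window(tbr, window)
    return PetMetrics(
        suv_mean=suv_mean,
        suv_max=suv_max,
        suv_slope=suv_slope,
        suv_intercept=suv_intercept,
        tbr_mean=tbr_mean,
        tbr_max=tbr_max,
        tbr_slope=tbr_slope,
        tbr_intercept=tbr_intercept,
        ttp_s=time_to_peak(lesion),
    )
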