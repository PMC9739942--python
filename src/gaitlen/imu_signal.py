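"""Raw tri-axial acceleration → segmented strides with per-stride features.

The estimators downstream consume scalar features of the acceleration
*magnitude* within each stride: the stride frequency F, the range a_r of the
magnitude, its extrema, mean and variance.  Working on the magnitude (the
Euclidean norm of the three axes) makes the whole pipeline invariant to how
the sensor was oriented on the body, which is the main practical appeal of
magnitude-based step-length models.

A stride is two consecutive steps of the same limb, so the segmenter pairs
detected step peaks with the same parity (peak i to peak i+2): treadmill
reference lengths are stride lengths of one limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

SENSOR_POSITIONS = ("upper_arm", "hand", "pelvis", "thigh", "other")

#: physiological stride-duration gate, seconds. Walking at 3-6 km/h produces
#: stride durations around 1 s; anything outside this band is a segmentation
#: artifact, not a stride.
STRIDE_DURATION_BOUNDS = (0.4, 4.0)


@dataclass(frozen=True)
class AccelTrace:
    """Timestamped tri-axial linear acceleration from one body-worn sensor.

    Parameters
    ----------
    t : array of float
        Sample timestamps, seconds, strictly increasing, length >= 2.
    ax, ay, az : arrays of float
        Linear acceleration per axis, m/s^2 (gravity already removed).
    position : str
        Body placement label, one of ``SENSOR_POSITIONS``.
    subject_id : str
        Opaque subject label.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    position: str = "other"
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.shape[0]
        if n < 2:
            raise ValueError(f"trace needs at least 2 samples, got {n}")
        for name in ("ax", "ay", "az"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length {getattr(self, name).shape[0]} != t length {n}")
        if not np.all(np.diff(self.t) > 0):
            i = int(np.argmin(np.diff(self.t) > 0))
            raise ValueError(f"timestamps not strictly increasing at index {i + 1}")
        for name in ("t", "ax", "ay", "az"):
            vals = getattr(self, name)
            if not np.all(np.isfinite(vals)):
                i = int(np.argmin(np.isfinite(vals)))
                raise ValueError(f"non-finite value in {name} at index {i}")
        if self.position not in SENSOR_POSITIONS:
            raise ValueError(f"unknown position {self.position!r}; expected one of {SENSOR_POSITIONS}")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate, Hz."""
        return float(1.0 / np.median(np.diff(self.t)))

    def rotated(self, rotation: np.ndarray) -> "AccelTrace":
        """Return a copy with the 3-D ``rotation`` matrix applied to the axes."""
        R = np.asarray(rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        xyz = R @ np.vstack([self.ax, self.ay, self.az])
        return AccelTrace(self.t, xyz[0], xyz[1], xyz[2], self.position, self.subject_id)


@dataclass
class StrideRecord:
    """One segmented stride and the features every estimator consumes.

    Sample indices are half-open ``[start_idx, end_idx)``.  ``a_v`` is the
    population variance of the magnitude within the stride; ``F`` is the
    stride frequency 1/duration in Hz; ``d_ref`` holds the optional reference
    stride length in meters.
    """

    start_idx: int
    end_idx: int
    duration: float
    F: float
    a_max: float
    a_min: float
    a_r: float
    a_mean: float
    a_v: float
    d_ref: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stride duration must be positive")
        if self.F <= 0:
            raise ValueError("stride frequency must be positive")
        if abs(self.F * self.duration - 1.0) > 1e-9:
            raise ValueError("F must equal 1/duration")
        if self.a_r < 0 or abs(self.a_r - (self.a_max - self.a_min)) > 1e-9:
            raise ValueError("a_r must equal a_max - a_min and be non-negative")
        if self.a_v < 0:
            raise ValueError("a_v must be non-negative")


@dataclass
class SegmentationConfig:
    """Peak-detector settings for stride segmentation.

    ``min_peak_distance`` is the minimum spacing between step peaks in
    seconds, ``min_prominence`` the minimum peak prominence in m/s^2, and
    ``smoothing_window`` the length in samples of the moving-average filter
    applied before peak picking (features are still computed on the
    unsmoothed magnitude, so smoothing cannot bias a_r).
    """

    min_peak_distance: float = 0.3
    min_prominence: float = 0.5
    smoothing_window: int = 10
    duration_bounds: tuple[float, float] = STRIDE_DURATION_BOUNDS


def magnitude(trace: AccelTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the acceleration vector, m/s^2.

    Rotation-invariant: rotating the raw axes leaves the magnitude unchanged,
    which is why magnitude-based estimators are unaffected by sensor
    orientation.
    """
    return np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)


def smooth(values: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average with a shrinking window at the start.

    Output length equals input length; sample i is the mean of the last
    ``window`` samples up to and including i (fewer at the start, where only
    a partial window exists).  A constant series maps to itself.
    """
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if x.shape[0] < window:
        raise ValueError(f"series length {x.shape[0]} shorter than window {window}")
    csum = np.cumsum(np.insert(x, 0, 0.0))
    out = np.empty_like(x)
    n = x.shape[0]
    widths = np.minimum(np.arange(1, n + 1), window)
    starts = np.arange(1, n + 1) - widths
    out = (csum[1:] - csum[starts]) / widths
    return out


def stride_features(
    mag_window: Sequence[float], t_start: float, t_end: float
) -> tuple[float, float, float, float, float, float, float]:
    """Feature tuple (F, a_max, a_min, a_r, a_mean, a_v, duration) for one window.

    ``a_v`` is the population (divide-by-n) variance: a stride window is the
    full population of its samples, and keeping the convention fixed keeps
    fitted constants comparable across runs.
    """
    w = np.asarray(mag_window, dtype=float)
    if w.shape[0] < 2:
        raise ValueError("stride window needs at least 2 samples")
    duration = float(t_end - t_start)
    if duration <= 0:
        raise ValueError("degenerate stride window: duration must be positive")
    a_max = float(np.max(w))
    a_min = float(np.min(w))
    a_mean = float(np.mean(np.abs(w)))
    a_v = float(np.var(w))
    return (1.0 / duration, a_max, a_min, a_max - a_min, a_mean, a_v, duration)


def segment_strides(
    mag: Sequence[float],
    t: Sequence[float],
    config: SegmentationConfig | None = None,
) -> list[StrideRecord]:
    """Segment an acceleration-magnitude series into strides.

    Step peaks are local maxima of the smoothed magnitude subject to a
    minimum inter-peak distance and prominence.  Strides are the half-open
    intervals from peak i to peak i+2 with i even (same parity, so one stride
    spans two steps and intervals do not overlap).  Features are computed on
    the *unsmoothed* magnitude.  Candidates with duration outside the
    physiological gate are dropped.

    Returns an empty list (with a log warning) when fewer than 3 peaks are
    found.
    """
    config = config or SegmentationConfig()
    m = np.asarray(mag, dtype=float)
    tt = np.asarray(t, dtype=float)
    if m.shape[0] != tt.shape[0]:
        raise ValueError("mag and t must have the same length")

    window = min(config.smoothing_window, m.shape[0])
    sm = smooth(m, window)
    fs = 1.0 / np.median(np.diff(tt))
    distance = max(1, int(round(config.min_peak_distance * fs)))
    peaks, _ = find_peaks(sm, distance=distance, prominence=config.min_prominence)
    if peaks.shape[0] < 3:
        logger.warning("only %d peaks found; no strides segmented", peaks.shape[0])
        return []

    lo, hi = config.duration_bounds
    strides: list[StrideRecord] = []
    for k in range(0, peaks.shape[0] - 2, 2):
        i0, i1 = int(peaks[k]), int(peaks[k + 2])
        duration = tt[i1] - tt[i0]
        if not (lo <= duration <= hi):
            continue
        F, a_max, a_min, a_r, a_mean, a_v, dur = stride_features(m[i0:i1], tt[i0], tt[i1])
        strides.append(
            StrideRecord(
                start_idx=i0, end_idx=i1, duration=dur, F=F,
                a_max=a_max, a_min=a_min, a_r=a_r, a_mean=a_mean, a_v=a_v,
            )
        )
    return strides
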