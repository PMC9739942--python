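"""Optical-marker trajectory processing and heel-based reference stride lengths.

Marker positions from a motion-capture system are differentiated with finite
differences (central in the interior, one-sided at the endpoints) and the
derivatives are smoothed with a 10-point moving average — derivative first,
then filter.  Reference stride lengths come from the heel marker: stance
phases are detected where the filtered heel speed drops below a threshold,
and the stride length is the ground-plane displacement between consecutive
stance centroids, plus belt travel when walking on a treadmill.

Coordinate convention: ground plane is x-y, vertical is z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imu_signal import smooth

logger = logging.getLogger(__name__)

HEEL_MARKER = "M7"


@dataclass(frozen=True)
class MarkerTrajectory:
    """3-D trajectory of one motion-capture marker (positions in meters)."""

    marker_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.shape[0]
        for name in ("x", "y", "z"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch with t")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps not strictly increasing")
        for name in ("t", "x", "y", "z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) position array."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class KinematicSeries:
    """Filtered velocity and acceleration derived from a marker trajectory."""

    t: np.ndarray
    velocity: np.ndarray      # (n, 3), m/s
    acceleration: np.ndarray  # (n, 3), m/s^2


@dataclass
class StanceConfig:
    """Stance detection settings for reference stride lengths.

    ``speed_threshold`` (m/s) marks samples as stance when the filtered heel
    speed is below it; a stance phase must last at least ``min_stance``
    seconds.  ``belt_speed`` (m/s), when set, adds belt travel between stance
    centroids — on a treadmill the foot barely moves in the room frame, so
    the stride length is carried almost entirely by the belt.
    """

    speed_threshold: float = 0.2
    min_stance: float = 0.1
    belt_speed: float | None = None
    filter_window: int = 10


def finite_difference(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Numerical derivative: central differences inside, one-sided at the ends.

    Exact for linear series everywhere and for quadratics at interior points.
    Requires length >= 3 and distinct timestamps.
    """
    v = np.asarray(values, dtype=float)
    tt = np.asarray(t, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("finite_difference needs at least 3 samples")
    dt = np.diff(tt)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    out = np.empty_like(v)
    out[1:-1] = (v[2:] - v[:-2]) / (tt[2:] - tt[:-2])
    out[0] = (v[1] - v[0]) / (tt[1] - tt[0])
    out[-1] = (v[-1] - v[-2]) / (tt[-1] - tt[-2])
    return out


def kinematics(traj: MarkerTrajectory, filter_window: int = 10) -> KinematicSeries:
    """Velocity and acceleration of a marker: differentiate, then smooth.

    Each axis is differentiated with :func:`finite_difference` and filtered
    with the trailing moving average of :func:`gaitlen.imu_signal.smooth`;
    the acceleration repeats the same pair on the filtered velocity.
    """
    pos = traj.positions
    vel = np.column_stack(
        [smooth(finite_difference(pos[:, k], traj.t), filter_window) for k in range(3)]
    )
    acc = np.column_stack(
        [smooth(finite_difference(vel[:, k], traj.t), filter_window) for k in range(3)]
    )
    return KinematicSeries(t=traj.t.copy(), velocity=vel, acceleration=acc)


def _stance_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, end)."""
    padded = np.concatenate([[False], below, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.shape[0], 2)]


def reference_strides(
    heel: MarkerTrajectory, config: StanceConfig | None = None
) -> list[tuple[tuple[float, float], float]]:
    """Reference stride lengths from the heel marker.

    Returns ``[((t_start, t_end), d_ref), ...]`` where the interval spans
    consecutive stance-phase centroids and ``d_ref`` is the ground-plane
    displacement between them (plus ``belt_speed * interval`` on a
    treadmill), in meters.  Fewer than two stance phases yields an empty
    list and a warning.
    """
    config = config or StanceConfig()
    kin = kinematics(heel, config.filter_window)
    speed = np.linalg.norm(kin.velocity, axis=1)
    runs = _stance_runs(speed < config.speed_threshold)

    centroids: list[tuple[float, np.ndarray]] = []
    pos = heel.positions
    for i0, i1 in runs:
        if heel.t[i1 - 1] - heel.t[i0] < config.min_stance:
            continue
        centroids.append((float(np.mean(heel.t[i0:i1])), np.mean(pos[i0:i1], axis=0)))

    if len(centroids) < 2:
        logger.warning("fewer than 2 stance phases detected; no reference strides")
        return []

    out = []
    for (t0, p0), (t1, p1) in zip(centroids, centroids[1:]):
        d = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        if config.belt_speed is not None:
            d += config.belt_speed * (t1 - t0)
        out.append(((t0, t1), d))
    return out
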