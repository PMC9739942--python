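"""Adaptive per-speed constant selection for the stride-frequency model.

Stride frequency and the acceleration-magnitude range both track walking
speed, so a profile calibrated at one speed misfits at another.  The
adaptive scheme processes strides in windows of N (default 10): for each
window it computes the mean stride frequency and mean magnitude range,
matches them against the stored per-speed profile centroids, and estimates
the window's stride lengths with the nearest profile's constants.

Matching is nearest-centroid in a z-scored 2-D feature space; both features
are scaled by the spread of the profile centroids so neither dominates by
units.  Ties go to the profile with the lower mean stride frequency.
Selection is causal within the window: window w's choice applies to window w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import SpeedProfile
from .imu_signal import StrideRecord
from .models import estimate_proposed


@dataclass
class AdaptiveConfig:
    """Settings for the adaptive selector: window length N in strides."""

    N: int = 10

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")


def _profile_scales(profiles: list[SpeedProfile]) -> tuple[float, float]:
    """Per-feature scale = spread of profile centroids (1.0 when degenerate)."""
    fs = np.array([p.mean_F for p in profiles])
    ars = np.array([p.mean_a_r for p in profiles])
    s_f = float(np.std(fs))
    s_ar = float(np.std(ars))
    return (s_f if s_f > 0 else 1.0, s_ar if s_ar > 0 else 1.0)


def select_profile(
    window_strides: list[StrideRecord],
    profiles: list[SpeedProfile],
    config: AdaptiveConfig | None = None,
) -> SpeedProfile:
    """Profile whose stored (mean_F, mean_a_r) best matches the window.

    Both features are z-scored by the pooled spread of the profile centroids
    before the Euclidean distance; ties break toward the lower mean_F, so the
    result does not depend on the order of ``profiles``.
    """
    if not profiles:
        raise ValueError("at least one speed profile is required")
    if not window_strides:
        raise ValueError("window must contain at least one stride")
    wf = float(np.mean([s.F for s in window_strides]))
    war = float(np.mean([s.a_r for s in window_strides]))
    s_f, s_ar = _profile_scales(profiles)

    best: SpeedProfile | None = None
    best_key: tuple[float, float] | None = None
    for p in profiles:
        dist = np.hypot((wf - p.mean_F) / s_f, (war - p.mean_a_r) / s_ar)
        key = (float(dist), p.mean_F)
        if best_key is None or key < best_key:
            best, best_key = p, key
    assert best is not None
    return best


def estimate_adaptive(
    strides: list[StrideRecord],
    profiles: list[SpeedProfile],
    config: AdaptiveConfig | None = None,
) -> tuple[list[float], list[SpeedProfile]]:
    """Per-stride length estimates with per-window profile selection.

    Strides are processed in consecutive windows of N (the last window may
    be shorter); each window's strides are run through the adaptive model
    with its selected profile's constants.  Returns the estimates plus the
    profile chosen for each stride.
    """
    config = config or AdaptiveConfig()
    lengths: list[float] = []
    chosen: list[SpeedProfile] = []
    for i in range(0, len(strides), config.N):
        window = strides[i : i + config.N]
        profile = select_profile(window, profiles, config)
        c = profile.params.constants
        for s in window:
            lengths.append(estimate_proposed(s, c["K1"], c["K2"]))
            chosen.append(profile)
    return lengths, chosen
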