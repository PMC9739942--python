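"""Seeded synthetic gait: IMU traces, marker trajectories, benchmark rosters.

The generators emulate the structure of a treadmill/free-walking gait
dataset — per-stride periodic acceleration-magnitude signals decomposed
onto three sensor axes, a heel-marker trajectory with flat stance phases,
three walking speeds (slow/normal/fast, mapped to stride frequencies of
0.80/0.92/1.05 Hz) and a 21.64 m rectangular free-walking loop — with full
ground truth attached, so segmentation, calibration, the adaptive selector
and the derivation stage are all testable without any recorded data.

Within stride i of duration T_i the noiseless magnitude is

    m(tau) = b + A_i * sin(4*pi*tau/T_i) + asym * A_i * sin(2*pi*tau/T_i)

i.e. a step harmonic at 2 F_i plus a smaller stride harmonic at F_i (left/
right asymmetry), over a baseline b.  The three axes are the magnitude times
a fixed, seeded random unit direction, so the magnitude is exactly
rotation-controlled.  True stride lengths follow either the feature-linear
law d_i = K1* F_i + K2* a_r,i^0.1 + eps_i or an inverted-pendulum relation
on leg length.  Every draw comes from one numpy Generator seeded per
scenario, so identical scenarios are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .imu_signal import AccelTrace, StrideRecord, stride_features
from .marker_kinematics import MarkerTrajectory

#: default speed-label → stride frequency (Hz) mapping; monotone in speed
SPEED_FREQUENCIES = {"slow": 0.80, "normal": 0.92, "fast": 1.05}

#: default magnitude oscillation amplitude (m/s^2) per sensor position;
#: distal placements swing more than the trunk
POSITION_AMPLITUDES = {"hand": 4.0, "thigh": 3.0, "upper_arm": 2.5, "pelvis": 2.0, "other": 2.5}

#: amplitude multiplier per walking speed: faster gait accelerates harder,
#: so both stride frequency and magnitude range index walking speed
SPEED_AMPLITUDE_FACTORS = {"slow": 0.8, "normal": 1.0, "fast": 1.25}

POLYGON_LOOP_M = 21.64
#: rectangle sides (m) summing to the loop perimeter
POLYGON_SIDES = (6.82, 4.0)

TRUTH_MODELS = ("linear_in_features", "pendulum")


@dataclass
class GaitScenario:
    """Parameters of one synthetic walking trial.

    ``speed_label`` sets the stride frequency via ``SPEED_FREQUENCIES``
    unless ``stride_frequency_hz`` overrides it; ``magnitude_amplitude``
    likewise falls back to the per-position default.  ``true_k1``/``true_k2``
    are the feature-linear truth constants; ``length_noise_sd`` is the
    standard deviation (m) of the per-stride length noise eps_i.
    """

    seed: int = 0
    n_strides: int = 100
    speed_label: str = "normal"
    stride_frequency_hz: float | None = None
    position: str = "pelvis"
    magnitude_amplitude: float | None = None
    baseline: float | None = None  # default: 1.35 * amplitude + 1, keeps magnitude positive
    asymmetry: float = 0.3
    noise_sd: float = 0.2
    sampling_rate: float = 100.0
    freq_jitter: float = 0.03
    amp_jitter: float = 0.05
    truth_model: str = "linear_in_features"
    true_k1: float = 0.80
    true_k2: float = 0.25
    leg_length: float = 1.0
    length_noise_sd: float = 0.02
    route: str = "treadmill"
    loop_length_m: float = POLYGON_LOOP_M
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.sampling_rate < 20:
            raise ValueError("sampling_rate must be >= 20 Hz")
        if self.noise_sd < 0 or self.length_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.truth_model not in TRUTH_MODELS:
            raise ValueError(f"unknown truth model {self.truth_model!r}")
        if self.route not in ("treadmill", "polygon", "overground"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.stride_frequency_hz is None and self.speed_label not in SPEED_FREQUENCIES:
            raise ValueError(f"unknown speed label {self.speed_label!r}")

    @property
    def frequency(self) -> float:
        return (
            self.stride_frequency_hz
            if self.stride_frequency_hz is not None
            else SPEED_FREQUENCIES[self.speed_label]
        )

    @property
    def amplitude(self) -> float:
        if self.magnitude_amplitude is not None:
            return self.magnitude_amplitude
        factor = SPEED_AMPLITUDE_FACTORS.get(self.speed_label, 1.0)
        return POSITION_AMPLITUDES[self.position] * factor

    @property
    def effective_baseline(self) -> float:
        """Baseline magnitude; the default clears the oscillation trough."""
        if self.baseline is not None:
            return self.baseline
        return 1.35 * self.amplitude + 1.0


def _stride_timing(scenario: GaitScenario, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride durations and amplitudes with multiplicative jitter."""
    F0 = scenario.frequency
    f = F0 * (1.0 + scenario.freq_jitter * rng.standard_normal(scenario.n_strides))
    f = np.clip(f, 0.3 * F0, 3.0 * F0)
    amps = scenario.amplitude * (
        1.0 + scenario.amp_jitter * rng.standard_normal(scenario.n_strides)
    )
    amps = np.clip(amps, 0.1 * scenario.amplitude, None)
    return 1.0 / f, amps


def _true_length(
    scenario: GaitScenario,
    F: float,
    a_r: float,
    rng: np.random.Generator,
) -> float:
    if scenario.truth_model == "linear_in_features":
        d = scenario.true_k1 * F + scenario.true_k2 * a_r**0.1
    else:
        # inverted pendulum: vertical excursion from the step-harmonic
        # acceleration amplitude at angular frequency 4*pi*F
        amp = a_r / 2.6  # a_r of the two-harmonic shape is ~2.6 * A
        delta = min(2.0 * amp / (4.0 * np.pi * F) ** 2, 0.5 * scenario.leg_length)
        d = 4.0 * np.sqrt(2.0 * scenario.leg_length * delta - delta**2)
    return d + scenario.length_noise_sd * rng.standard_normal()


def generate_trace(scenario: GaitScenario) -> tuple[AccelTrace, list[StrideRecord]]:
    """Synthesize one trial: the tri-axial trace plus ground-truth strides.

    The returned stride records carry features computed on the *noiseless*
    magnitude over each true stride window and a filled ``d_ref``.
    Deterministic per scenario (same scenario → bitwise-identical output).
    """
    rng = np.random.default_rng(scenario.seed)
    durations, amps = _stride_timing(scenario, rng)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    total = boundaries[-1]
    n = int(np.floor(total * scenario.sampling_rate))
    t = np.arange(n) / scenario.sampling_rate

    stride_of = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, scenario.n_strides - 1)
    tau = t - boundaries[stride_of]
    T = durations[stride_of]
    A = amps[stride_of]
    clean = (
        scenario.effective_baseline
        + A * np.sin(4.0 * np.pi * tau / T)
        + scenario.asymmetry * A * np.sin(2.0 * np.pi * tau / T)
    )
    noisy = np.abs(clean + scenario.noise_sd * rng.standard_normal(n))

    # fixed random unit direction: magnitude is exactly rotation-controlled
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    trace = AccelTrace(
        t=t, ax=noisy * u[0], ay=noisy * u[1], az=noisy * u[2],
        position=scenario.position, subject_id=scenario.subject_id,
    )

    strides: list[StrideRecord] = []
    for i in range(scenario.n_strides):
        i0 = int(np.searchsorted(t, boundaries[i], side="left"))
        i1 = int(np.searchsorted(t, boundaries[i + 1], side="left"))
        if i1 - i0 < 2:
            continue
        F, a_max, a_min, a_r, a_mean, a_v, dur = stride_features(
            clean[i0:i1], boundaries[i], boundaries[i + 1]
        )
        strides.append(
            StrideRecord(
                start_idx=i0, end_idx=i1, duration=dur, F=F,
                a_max=a_max, a_min=a_min, a_r=a_r, a_mean=a_mean, a_v=a_v,
                d_ref=_true_length(scenario, F, a_r, rng),
            )
        )
    return trace, strides


def _polygon_point(s: float, sides: tuple[float, float] = POLYGON_SIDES) -> np.ndarray:
    """Map arc length s along the rectangle perimeter to an (x, y) point."""
    L, W = sides
    per = 2 * (L + W)
    s = s % per
    if s < L:
        return np.array([s, 0.0])
    if s < L + W:
        return np.array([L, s - L])
    if s < 2 * L + W:
        return np.array([L - (s - L - W), W])
    return np.array([0.0, W - (s - 2 * L - W)])


def generate_markers(
    scenario: GaitScenario,
    stride_lengths: list[float] | None = None,
    stance_fraction: float = 0.35,
    marker_noise_sd: float = 0.0,
) -> dict[str, MarkerTrajectory]:
    """Synthesize the eight anatomical-landmark trajectories (M1–M8).

    The heel (M7) alternates flat stance phases with smooth swing advances,
    so stance-based reference stride recovery sees the configured lengths.
    On a treadmill the stance points stay near the origin (net displacement
    near zero — the belt carries the distance); on the free-walking polygon
    the heel progresses along the rectangular loop.  Other markers ride the
    body path with phase-offset gait-harmonic oscillations.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    durations, _ = _stride_timing(scenario, np.random.default_rng(scenario.seed))
    if stride_lengths is None:
        stride_lengths = [scenario.true_k1 * (1.0 / d) + scenario.true_k2 for d in durations]
    if len(stride_lengths) != scenario.n_strides:
        raise ValueError("stride_lengths must match n_strides")

    fs = scenario.sampling_rate
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    n = int(np.floor(boundaries[-1] * fs))
    t = np.arange(n) / fs

    # heel arc-length along the walking path: flat in stance, cosine-smooth
    # advance in swing
    s_arc = np.empty(n)
    starts = np.concatenate([[0.0], np.cumsum(stride_lengths)])
    stride_of = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, scenario.n_strides - 1)
    tau = t - boundaries[stride_of]
    T = durations[stride_of]
    L = np.asarray(stride_lengths)[stride_of]
    s0 = starts[stride_of]
    stance = tau < stance_fraction * T
    swing_phase = (tau - stance_fraction * T) / ((1.0 - stance_fraction) * T)
    s_arc = np.where(stance, s0, s0 + L * 0.5 * (1.0 - np.cos(np.pi * np.clip(swing_phase, 0, 1))))
    z = np.where(stance, 0.0, 0.06 * np.sin(np.pi * np.clip(swing_phase, 0, 1)))

    if scenario.route == "polygon":
        xy = np.array([_polygon_point(s) for s in s_arc])
        hx, hy = xy[:, 0], xy[:, 1]
    elif scenario.route == "overground":
        # straight-line walk along x; stance points at the cumulative lengths
        hx = s_arc.copy()
        hy = np.zeros(n)
    else:
        # treadmill: the belt returns the foot, so world-frame stance points
        # sit at the origin and the swing excursion cancels out
        hx = np.where(stance, 0.0, (s_arc - s0) - L * np.clip(swing_phase, 0, 1))
        hy = np.zeros(n)
    if marker_noise_sd > 0:
        hx = hx + marker_noise_sd * rng.standard_normal(n)
        hy = hy + marker_noise_sd * rng.standard_normal(n)
        z = z + marker_noise_sd * rng.standard_normal(n)

    markers = {"M7": MarkerTrajectory("M7", t, hx, hy, z)}

    # remaining landmarks: body path plus phase-offset gait harmonics
    if scenario.route == "polygon":
        body = np.array([_polygon_point(s) for s in s0 + 0.5 * L])
        bx, by = body[:, 0], body[:, 1]
    elif scenario.route == "overground":
        bx = s0 + 0.5 * L
        by = np.zeros(n)
    else:
        bx = np.zeros(n)
        by = np.zeros(n)
    F0 = scenario.frequency
    heights = {"M1": 1.45, "M2": 1.15, "M3": 0.95, "M4": 1.0, "M5": 0.5, "M6": 0.1, "M8": 0.05}
    for k, (mid, h0) in enumerate(heights.items()):
        phase = 2.0 * np.pi * k / 8.0
        osc = 0.04 * np.sin(2.0 * np.pi * F0 * t + phase)
        osc2 = 0.02 * np.sin(4.0 * np.pi * F0 * t + phase)
        noise = marker_noise_sd * rng.standard_normal((n, 3)) if marker_noise_sd > 0 else 0.0
        xyz = np.column_stack([bx + osc, by + osc2, h0 + osc2])
        if marker_noise_sd > 0:
            xyz = xyz + noise
        markers[mid] = MarkerTrajectory(mid, t, xyz[:, 0], xyz[:, 1], xyz[:, 2])
    return markers


def generate_speed_set(
    seed: int,
    n_strides: int = 120,
    subject_id: str = "S01",
    position: str = "pelvis",
    truth_by_speed: dict[str, tuple[float, float]] | None = None,
    **overrides,
) -> dict[str, tuple[AccelTrace, list[StrideRecord]]]:
    """One trial per walking speed, optionally with speed-specific truth
    constants (how the adaptive scheme's premise — constants drift with
    speed — is realized synthetically)."""
    out = {}
    for j, label in enumerate(SPEED_FREQUENCIES):
        k1, k2 = (truth_by_speed or {}).get(label, (None, None))
        kwargs = dict(
            seed=seed + j, n_strides=n_strides, speed_label=label,
            subject_id=subject_id, position=position,
        )
        if k1 is not None:
            kwargs.update(true_k1=k1, true_k2=k2)
        kwargs.update(overrides)
        out[label] = generate_trace(GaitScenario(**kwargs))
    return out


def generate_derivation_dataset(
    seed: int,
    n_strides: int = 400,
    base_constant: float = 1.0,
    freq_jitter: float = 0.08,
    length_noise_sd: float = 0.01,
    kinematic_noise_sd: float = 0.05,
):
    """Strides + marker kinematics where stride frequency drives the
    per-stride constant K — the derivation stage's recoverable ground truth.

    Reference lengths are d_i = (c * F_i) * a_r,i^0.1 + eps, so the implied
    constant K_i = d_i / a_r,i^0.1 is linear in stride frequency; the marker
    kinematic channels are band-limited noise.  Returns
    ``(strides, intervals, kin)`` ready for matrix assembly.
    """
    from .imu_signal import smooth
    from .marker_kinematics import KinematicSeries

    scenario = GaitScenario(
        seed=seed, n_strides=n_strides, freq_jitter=freq_jitter,
        length_noise_sd=0.0, noise_sd=0.0,
    )
    rng = np.random.default_rng(seed + 10_000)
    _, strides = generate_trace(scenario)
    for s in strides:
        s.d_ref = base_constant * s.F * s.a_r**0.1 + length_noise_sd * rng.standard_normal()

    durations, _ = _stride_timing(scenario, np.random.default_rng(seed))
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    intervals = list(zip(boundaries[:-1], boundaries[1:]))[: len(strides)]

    fs = scenario.sampling_rate
    n = int(np.floor(boundaries[-1] * fs))
    t = np.arange(n) / fs
    vel = np.column_stack(
        [smooth(kinematic_noise_sd * rng.standard_normal(n), 15) for _ in range(3)]
    )
    acc = np.column_stack(
        [smooth(kinematic_noise_sd * rng.standard_normal(n), 15) for _ in range(3)]
    )
    kin = KinematicSeries(t=t, velocity=vel, acceleration=acc)
    return strides, intervals, kin


DEFAULT_ROSTER_POSITIONS = ("upper_arm", "hand", "pelvis", "thigh")
DEFAULT_ROSTER_SPEEDS = ("slow", "normal", "fast", "polygon")


def generate_benchmark_suite(
    seed: int,
    out_dir: str | Path,
    n_subjects: int = 3,
    positions: tuple[str, ...] = DEFAULT_ROSTER_POSITIONS,
    speeds: tuple[str, ...] = DEFAULT_ROSTER_SPEEDS,
    n_strides: int = 60,
) -> dict:
    """Write a benchmark roster of synthetic trials to disk.

    Layout: ``traces/<subject>_<position>_<speed>.csv`` (one per trial,
    default 3 subjects x 4 positions x 4 speeds = 48 files),
    ``refs/<same>.csv`` with the ground-truth stride records, and a
    ``manifest.yaml`` recording the seed, truth parameters and file list.
    Deterministic per seed.  Returns the manifest dict.
    """
    from .io_cli import write_strides, write_trace

    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "refs").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "trials": []}
    trial_seed = seed
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        for position in positions:
            for speed in speeds:
                trial_seed += 1
                scenario = GaitScenario(
                    seed=trial_seed,
                    n_strides=n_strides,
                    speed_label=speed if speed != "polygon" else "normal",
                    route="polygon" if speed == "polygon" else "treadmill",
                    position=position,
                    subject_id=subject,
                )
                trace, strides = generate_trace(scenario)
                name = f"{subject}_{position}_{speed}.csv"
                write_trace(out / "traces" / name, trace)
                write_strides(out / "refs" / name, strides, trace.t)
                manifest["trials"].append(
                    {
                        "subject": subject,
                        "position": position,
                        "speed": speed,
                        "seed": trial_seed,
                        "trace": f"traces/{name}",
                        "refs": f"refs/{name}",
                        "true_k1": scenario.true_k1,
                        "true_k2": scenario.true_k2,
                        "n_strides": len(strides),
                    }
                )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
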