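"""Step/stride-length estimators as pure functions of stride features.

Six models, all mapping per-stride features (stride frequency F in Hz and
scalar statistics of the acceleration magnitude, m/s^2) to a length in
meters through a small set of tunable constants fitted by least squares:

======== =============================================  ==========
model    equation                                       constants
======== =============================================  ==========
base     d = K * a_r^0.1                                K
proposed d = K1 * F + K2 * a_r^0.1                      K1, K2
mikov    d = (K / F) * (a_max - a_min)^(1/4)            K
bylemans d = 0.1 * a_mean * (K / F) * a_r^(1/2.7)       K
shin     d = K1 * F + K2 * a_v + K3                     K1..K3
sharp_yu d = K1 * h^K2 * (a_max - a_min)^K3 * F^K4      K1..K4
======== =============================================  ==========

The literature formulas are written with *step* features and, for some
models, vertical acceleration.  Here every model is fitted and evaluated on
*stride* features of the acceleration *magnitude*: the factor-of-two between
step and stride frequency is absorbed into the fitted constants, and using
the magnitude keeps the comparison orientation-independent (the sensors'
orientation on the body is arbitrary).  The Bylemans formula's typography is
ambiguous; the canonical grouping above parallels the Mikov fraction-plus-
root form, and an alternate grouping d = 0.1*a_mean*K*(F*a_r)^(-1/2.7) is
selectable via ``bylemans_variant="joint_root"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .imu_signal import StrideRecord

MODEL_IDS = ("base", "proposed", "mikov", "bylemans", "shin_park", "sharp_yu")

#: constants each model requires, in canonical order
MODEL_CONSTANTS: dict[str, tuple[str, ...]] = {
    "base": ("K",),
    "proposed": ("K1", "K2"),
    "mikov": ("K",),
    "bylemans": ("K",),
    "shin_park": ("K1", "K2", "K3"),
    "sharp_yu": ("K1", "K2", "K3", "K4"),
}

BYLEMANS_VARIANTS = ("canonical", "joint_root")


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics of one subject (height and leg length in meters)."""

    subject_id: str
    height: float
    leg_length: float = 0.0

    def __post_init__(self) -> None:
        if not (0.5 < self.height < 2.5):
            raise ValueError(f"implausible height {self.height} m")


@dataclass
class ModelParams:
    """Fitted constants of one model in one calibration context.

    ``context`` labels the calibration scope (subject, sensor position,
    speed set); ``diagnostics`` carries fit bookkeeping such as the number of
    strides and residual sum of squares.
    """

    model_id: str
    constants: dict[str, float]
    context: dict[str, str] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        expected = set(MODEL_CONSTANTS[self.model_id])
        got = set(self.constants)
        if got != expected:
            raise ValueError(
                f"{self.model_id} requires constants {sorted(expected)}, got {sorted(got)}"
            )


def _check_ar(a_r: float) -> None:
    if a_r < 0:
        raise ValueError("a_r must be non-negative")


def estimate_base(stride: StrideRecord, K: float) -> float:
    """d = K * a_r^0.1 (tenth root of the magnitude range)."""
    _check_ar(stride.a_r)
    return K * stride.a_r**0.1


def estimate_proposed(stride: StrideRecord, K1: float, K2: float) -> float:
    """d = K1 * F + K2 * a_r^0.1 — the stride-frequency-extended model."""
    _check_ar(stride.a_r)
    if stride.F <= 0:
        raise ValueError("F must be positive")
    return K1 * stride.F + K2 * stride.a_r**0.1


def estimate_mikov(stride: StrideRecord, K: float) -> float:
    """d = (K / F) * (a_max - a_min)^(1/4)."""
    _check_ar(stride.a_r)
    if stride.F <= 0:
        raise ValueError("F must be positive")
    return (K / stride.F) * stride.a_r**0.25


def estimate_bylemans(stride: StrideRecord, K: float, variant: str = "canonical") -> float:
    """Bylemans-style estimate; see module docstring for the two groupings."""
    _check_ar(stride.a_r)
    if stride.F <= 0:
        raise ValueError("F must be positive")
    if variant == "canonical":
        return 0.1 * stride.a_mean * (K / stride.F) * stride.a_r ** (1.0 / 2.7)
    if variant == "joint_root":
        return 0.1 * stride.a_mean * K * (stride.F * stride.a_r) ** (-1.0 / 2.7)
    raise ValueError(f"unknown bylemans variant {variant!r}; expected one of {BYLEMANS_VARIANTS}")


def estimate_shin_park(stride: StrideRecord, K1: float, K2: float, K3: float) -> float:
    """d = K1 * F + K2 * a_v + K3 (affine in frequency and magnitude variance)."""
    if stride.a_v < 0:
        raise ValueError("a_v must be non-negative")
    return K1 * stride.F + K2 * stride.a_v + K3


def estimate_sharp_yu(
    stride: StrideRecord, subject: SubjectProfile, K1: float, K2: float, K3: float, K4: float
) -> float:
    """d = K1 * h^K2 * (a_max - a_min)^K3 * F^K4 (log-linear power law)."""
    if stride.F <= 0:
        raise ValueError("F must be positive")
    if stride.a_r == 0 and K3 < 0:
        raise ValueError("a_r = 0 with negative exponent K3")
    return K1 * subject.height**K2 * stride.a_r**K3 * stride.F**K4


def estimate(
    stride: StrideRecord,
    params: ModelParams,
    subject: SubjectProfile | None = None,
    bylemans_variant: str = "canonical",
) -> float:
    """Dispatch a stride through the model named in ``params``."""
    c = params.constants
    mid = params.model_id
    if mid == "base":
        return estimate_base(stride, c["K"])
    if mid == "proposed":
        return estimate_proposed(stride, c["K1"], c["K2"])
    if mid == "mikov":
        return estimate_mikov(stride, c["K"])
    if mid == "bylemans":
        return estimate_bylemans(stride, c["K"], variant=bylemans_variant)
    if mid == "shin_park":
        return estimate_shin_park(stride, c["K1"], c["K2"], c["K3"])
    if mid == "sharp_yu":
        if subject is None:
            raise ValueError("sharp_yu requires a SubjectProfile (user height)")
        return estimate_sharp_yu(stride, subject, c["K1"], c["K2"], c["K3"], c["K4"])
    raise ValueError(f"unknown model {mid!r}")


def estimate_many(
    strides: list[StrideRecord],
    params: ModelParams,
    subject: SubjectProfile | None = None,
    bylemans_variant: str = "canonical",
) -> list[float]:
    """Vector convenience wrapper over :func:`estimate`."""
    return [estimate(s, params, subject, bylemans_variant) for s in strides]
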