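"""Least-squares calibration of model constants and per-speed profiles.

Each trial's first minutes (default 300 s) tune the constants; the remainder
is held out for evaluation.  Single-constant models have the closed-form
projection K = sum(d * x) / sum(x^2); multi-constant models are ordinary
least squares on their natural regressors.  The Sharp-Yu power law is fitted
in log space; since height is constant within a subject, K2 is fixed to 1
and K1 absorbs the height term (predictions are unchanged).

Per-speed ``SpeedProfile`` objects — fitted constants of the adaptive model
plus the mean stride frequency and mean magnitude range of the tuning
strides — are what the adaptive selector matches against at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imu_signal import StrideRecord
from .models import MODEL_CONSTANTS, ModelParams, SubjectProfile, estimate_many


@dataclass(frozen=True)
class CalibrationSplit:
    """Tune/evaluate split of one trial: first ``tune_seconds`` tune, rest evaluate."""

    tune_seconds: float = 300.0

    def split(self, strides: list[StrideRecord], t: np.ndarray) -> tuple[list[StrideRecord], list[StrideRecord]]:
        """Partition strides by whether they start within the tuning window."""
        t0 = float(t[0])
        tune = [s for s in strides if t[s.start_idx] - t0 < self.tune_seconds]
        rest = [s for s in strides if t[s.start_idx] - t0 >= self.tune_seconds]
        return tune, rest


@dataclass
class SpeedProfile:
    """Per-(subject, speed) calibration record used by the adaptive selector."""

    subject_id: str
    speed_label: str
    params: ModelParams
    mean_F: float
    mean_a_r: float

    def __post_init__(self) -> None:
        if self.mean_F <= 0:
            raise ValueError("mean_F must be positive")
        if self.mean_a_r < 0:
            raise ValueError("mean_a_r must be non-negative")


def attach_references(
    strides: list[StrideRecord],
    t: np.ndarray,
    references: list[tuple[tuple[float, float], float]],
) -> list[StrideRecord]:
    """Attach reference lengths to segmented strides by time overlap.

    Each stride gets the d_ref of the reference interval containing its
    midpoint (detector and reference clocks must be shared).  Strides with
    no covering reference keep ``d_ref=None``.  Returns the same records,
    mutated, for chaining.
    """
    tt = np.asarray(t, dtype=float)
    for s in strides:
        mid = 0.5 * (tt[s.start_idx] + tt[min(s.end_idx, len(tt) - 1)])
        for (t0, t1), d in references:
            if t0 <= mid < t1:
                s.d_ref = d
                break
    return strides


class RankDeficientError(ValueError):
    """Raised when the least-squares design matrix is rank deficient."""


def _require_refs(strides: list[StrideRecord], n_constants: int) -> np.ndarray:
    d = np.array([s.d_ref for s in strides], dtype=float)
    need = max(5, n_constants + 2)
    if len(strides) < need or not np.all(np.isfinite(d)):
        raise ValueError(f"need >= {need} strides with finite d_ref, got {len(strides)}")
    return d


def _single_k_basis(model_id: str, strides: list[StrideRecord]) -> np.ndarray:
    """Per-stride basis value x such that d_est = K * x for single-K models."""
    F = np.array([s.F for s in strides])
    a_r = np.array([s.a_r for s in strides])
    a_mean = np.array([s.a_mean for s in strides])
    if model_id == "base":
        return a_r**0.1
    if model_id == "mikov":
        return a_r**0.25 / F
    if model_id == "bylemans":
        return 0.1 * a_mean * a_r ** (1.0 / 2.7) / F
    raise ValueError(f"{model_id} is not a single-constant model")


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficientError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear regressors among {names}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit(
    model_id: str,
    strides: list[StrideRecord],
    subject: SubjectProfile | None = None,
    context: dict[str, str] | None = None,
    refine_sharp_yu: bool = False,
) -> ModelParams:
    """Fit one model's constants to strides carrying reference lengths.

    Minimizes the sum of squared residuals (d_est - d_ref)^2 over the
    constants.  ``refine_sharp_yu`` optionally follows the log-space Sharp-Yu
    fit with a nonlinear least-squares polish in the original space.
    """
    names = MODEL_CONSTANTS.get(model_id)
    if names is None:
        raise ValueError(f"unknown model {model_id!r}")
    d = _require_refs(strides, len(names))

    if model_id in ("base", "mikov", "bylemans"):
        x = _single_k_basis(model_id, strides)
        denom = float(np.sum(x * x))
        if denom == 0:
            raise RankDeficientError("all basis values are zero; K is unidentifiable")
        constants = {"K": float(np.sum(d * x) / denom)}
    elif model_id == "proposed":
        F = np.array([s.F for s in strides])
        a = np.array([s.a_r for s in strides]) ** 0.1
        X = np.column_stack([F, a])
        beta = _ols(X, d, ["F", "a_r^0.1"])
        constants = {"K1": float(beta[0]), "K2": float(beta[1])}
    elif model_id == "shin_park":
        F = np.array([s.F for s in strides])
        a_v = np.array([s.a_v for s in strides])
        X = np.column_stack([F, a_v, np.ones_like(F)])
        beta = _ols(X, d, ["F", "a_v", "1"])
        constants = {"K1": float(beta[0]), "K2": float(beta[1]), "K3": float(beta[2])}
    elif model_id == "sharp_yu":
        if subject is None:
            raise ValueError("sharp_yu fit requires a SubjectProfile")
        a_r = np.array([s.a_r for s in strides])
        F = np.array([s.F for s in strides])
        if np.any(d <= 0) or np.any(a_r <= 0):
            raise ValueError("sharp_yu log-space fit requires positive d_ref and a_r")
        X = np.column_stack([np.ones_like(F), np.log(a_r), np.log(F)])
        beta = _ols(X, np.log(d), ["1", "log a_r", "log F"])
        # height is constant per subject, so K2 := 1 and K1 absorbs h^K2
        constants = {
            "K1": float(np.exp(beta[0]) / subject.height),
            "K2": 1.0,
            "K3": float(beta[1]),
            "K4": float(beta[2]),
        }
        if refine_sharp_yu:
            constants = _refine_sharp_yu(constants, strides, subject, d)
    else:  # pragma: no cover - exhaustive above
        raise AssertionError(model_id)

    params = ModelParams(model_id=model_id, constants=constants, context=dict(context or {}))
    est = np.array(estimate_many(strides, params, subject))
    params.diagnostics = {"n": float(len(strides)), "rss": float(np.sum((est - d) ** 2))}
    return params


def _refine_sharp_yu(
    constants: dict[str, float],
    strides: list[StrideRecord],
    subject: SubjectProfile,
    d: np.ndarray,
) -> dict[str, float]:
    """Nonlinear polish of the log-space Sharp-Yu fit in the original space."""
    from scipy.optimize import least_squares

    a_r = np.array([s.a_r for s in strides])
    F = np.array([s.F for s in strides])
    h = subject.height

    def resid(p: np.ndarray) -> np.ndarray:
        K1, K3, K4 = p
        return K1 * h * a_r**K3 * F**K4 - d

    x0 = np.array([constants["K1"], constants["K3"], constants["K4"]])
    sol = least_squares(resid, x0, method="lm")
    return {"K1": float(sol.x[0]), "K2": 1.0, "K3": float(sol.x[1]), "K4": float(sol.x[2])}


def make_profiles(
    trials_by_speed: dict[str, list[StrideRecord]],
    subject: SubjectProfile,
    context: dict[str, str] | None = None,
) -> list[SpeedProfile]:
    """One adaptive-model profile per walking speed.

    ``trials_by_speed`` maps speed label → tune-window strides (d_ref set).
    Each profile stores the fitted constants plus the mean stride frequency
    and mean magnitude range over those strides.
    """
    profiles = []
    for speed_label, strides in trials_by_speed.items():
        ctx = dict(context or {})
        ctx.update({"subject": subject.subject_id, "speed": speed_label})
        params = fit("proposed", strides, subject, context=ctx)
        profiles.append(
            SpeedProfile(
                subject_id=subject.subject_id,
                speed_label=speed_label,
                params=params,
                mean_F=float(np.mean([s.F for s in strides])),
                mean_a_r=float(np.mean([s.a_r for s in strides])),
            )
        )
    return profiles


def fit_polygon_style(
    model_id: str,
    tune_windows: list[list[StrideRecord]],
    subject: SubjectProfile | None = None,
    context: dict[str, str] | None = None,
) -> ModelParams:
    """Fit on the concatenation of tune windows across walking speeds.

    This is the free-walking calibration style: one parameter set per
    (subject, sensor position), with all treadmill speeds joined.
    """
    joined = [s for window in tune_windows for s in window]
    return fit(model_id, joined, subject, context=context)
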