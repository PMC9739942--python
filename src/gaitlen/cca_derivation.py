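"""Derivation stage: which kinematic parameter drives the tunable constant?

The base acceleration-magnitude model d = K * a_r^0.1 has a constant K that
drifts with walking speed.  To find the drivers of that drift, each stride
contributes one row to two matrices: X1 holds the per-stride constant
K = d_ref / a_r^0.1 implied by the reference length, and X2 holds candidate
kinematic parameters of a body-landmark marker — stride frequency, stride
duration, and the mean, median and range of the marker's acceleration and
velocity in each of the three axes (p = 20 columns).  Canonical correlation
analysis between X1 and X2 then ranks the candidates: with a single-column
X1 the first canonical correlation equals the multiple correlation of
regressing K on the candidates, and the X2 canonical weights (standardized
by column spread, since raw canonical coefficients are scale-dependent)
order the parameters by contribution.

Stride frequency ranking first is what motivates extending the model to
d = K1 * F + K2 * a_r^0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imu_signal import StrideRecord
from .marker_kinematics import KinematicSeries

logger = logging.getLogger(__name__)

STATS = ("mean", "median", "range")
AXES = ("x", "y", "z")

#: X2 column labels in canonical order: frequency, duration, then
#: {mean, median, range} x {x, y, z} for acceleration and velocity.
X2_LABELS: tuple[str, ...] = (
    "stride_frequency",
    "stride_duration",
    *[f"acceleration_{s}_{ax}" for s in STATS for ax in AXES],
    *[f"velocity_{s}_{ax}" for s in STATS for ax in AXES],
)

#: below this first canonical correlation a ranking is flagged as weak
WEAK_CORRELATION_THRESHOLD = 0.1


@dataclass
class DerivationMatrices:
    """Row-aligned X1 (per-stride constants) and X2 (candidate parameters)."""

    X1: np.ndarray  # (n, 1)
    X2: np.ndarray  # (n, p)
    labels: tuple[str, ...]
    n_dropped: int = 0


@dataclass
class CcaResult:
    """Canonical coefficients, correlations, and ranking inputs.

    ``A1``/``A2`` are coefficient matrices on the original (unstandardized)
    columns; ``standardized_A2`` rescales A2 by the column standard
    deviations so weights are comparable across differently scaled
    parameters.  ``correlations`` is non-increasing in [0, 1].
    """

    A1: np.ndarray
    A2: np.ndarray
    correlations: np.ndarray
    standardized_A2: np.ndarray
    labels: tuple[str, ...]
    dropped_labels: tuple[str, ...] = ()


def stride_intervals(strides: list[StrideRecord], t: np.ndarray) -> list[tuple[float, float]]:
    """Time interval (t_start, t_end) of each stride on its trace clock."""
    tt = np.asarray(t, dtype=float)
    return [(float(tt[s.start_idx]), float(tt[s.end_idx])) for s in strides]


def _window_stats(series: np.ndarray) -> list[float]:
    return [
        float(np.mean(series)),
        float(np.median(series)),
        float(np.max(series) - np.min(series)),
    ]


def build_matrices(
    strides: list[StrideRecord],
    intervals: list[tuple[float, float]],
    kin: KinematicSeries,
) -> DerivationMatrices:
    """Assemble X1 and X2 from strides (with d_ref) and marker kinematics.

    ``intervals`` gives each stride's (t_start, t_end) on the clock shared
    with ``kin``.  Strides with a_r = 0, without d_ref, or whose rows end up
    non-finite are dropped (logged).
    """
    if len(strides) != len(intervals):
        raise ValueError("strides and intervals must align")
    rows1, rows2 = [], []
    n_dropped = 0
    for s, (t0, t1) in zip(strides, intervals):
        if s.d_ref is None or s.a_r <= 0:
            n_dropped += 1
            logger.debug("dropping stride without d_ref or with a_r=0")
            continue
        mask = (kin.t >= t0) & (kin.t < t1)
        if mask.sum() < 2:
            n_dropped += 1
            continue
        row = [s.F, s.duration]
        for source in (kin.acceleration, kin.velocity):
            stats_by_axis = [_window_stats(source[mask, ax]) for ax in range(3)]
            for stat in range(3):
                for ax in range(3):
                    row.append(stats_by_axis[ax][stat])
        k = s.d_ref / s.a_r**0.1
        full = np.array([k] + row)
        if not np.all(np.isfinite(full)):
            n_dropped += 1
            continue
        rows1.append([k])
        rows2.append(row)
    if n_dropped:
        logger.info("dropped %d strides during matrix assembly", n_dropped)
    return DerivationMatrices(
        X1=np.array(rows1, dtype=float),
        X2=np.array(rows2, dtype=float),
        labels=X2_LABELS,
        n_dropped=n_dropped,
    )


def _check_rank(Z: np.ndarray, labels: tuple[str, ...], tol: float = 1e-8) -> None:
    """Reject rank-deficient standardized blocks, naming dependent columns.

    Rank-revealing QR with column pivoting: the pivots beyond the numerical
    rank are the columns expressible through the ones before them.
    """
    from scipy.linalg import qr

    _, R, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0]))
    if rank < Z.shape[1]:
        dep = [labels[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient block; linearly dependent columns: {dep}")


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    """Inverse matrix square root of a symmetric positive-definite matrix."""
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, 1e-14 * float(np.max(w)))
    return V @ np.diag(w**-0.5) @ V.T


def cca(X1: np.ndarray, X2: np.ndarray, labels: tuple[str, ...] | None = None) -> CcaResult:
    """Classical (Hotelling) canonical correlation analysis via whitening + SVD.

    Columns are centered and scaled to unit variance internally; zero-
    variance X2 columns are dropped with a warning.  Returns min(p1, p2)
    canonical pairs with correlations sorted non-increasing in [0, 1].
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.ndim == 2 and X1.shape[0] == 1:
        X1 = X1.T
    n = X1.shape[0]
    if X2.shape[0] != n:
        raise ValueError("X1 and X2 must have the same number of rows")
    labels = tuple(labels) if labels is not None else tuple(f"x{j}" for j in range(X2.shape[1]))

    sd2 = np.std(X2, axis=0, ddof=1)
    keep = sd2 > 0
    dropped = tuple(l for l, k in zip(labels, keep) if not k)
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
    X2 = X2[:, keep]
    kept_labels = tuple(l for l, k in zip(labels, keep) if k)
    sd2 = sd2[keep]
    if n <= X2.shape[1] + 1:
        raise ValueError(f"need more rows ({n}) than X2 columns + 1 ({X2.shape[1] + 1})")

    sd1 = np.std(X1, axis=0, ddof=1)
    if np.any(sd1 == 0):
        raise ValueError("X1 has zero variance")

    Z1 = (X1 - X1.mean(axis=0)) / sd1
    Z2 = (X2 - X2.mean(axis=0)) / sd2
    _check_rank(Z2, kept_labels)
    C11 = Z1.T @ Z1 / (n - 1)
    C22 = Z2.T @ Z2 / (n - 1)
    C12 = Z1.T @ Z2 / (n - 1)

    W1 = _inv_sqrt(C11)
    W2 = _inv_sqrt(C22)
    U, svals, Vt = np.linalg.svd(W1 @ C12 @ W2)
    k = min(Z1.shape[1], Z2.shape[1])
    correlations = np.clip(svals[:k], 0.0, 1.0)

    A1_std = W1 @ U[:, :k]
    A2_std = W2 @ Vt.T[:, :k]
    # back to original-variable scale; standardized weights are the
    # unit-variance-space ones, which is what the ranking compares
    A1 = A1_std / sd1[:, None]
    A2 = A2_std / sd2[:, None]
    return CcaResult(
        A1=A1,
        A2=A2,
        correlations=correlations,
        standardized_A2=A2_std,
        labels=kept_labels,
        dropped_labels=dropped,
    )


def rank_parameters(result: CcaResult) -> list[tuple[str, float]]:
    """Candidate parameters ordered by |standardized first-pair weight|.

    Deterministic: ties break by column order.  A warning is logged when the
    first canonical correlation is below ``WEAK_CORRELATION_THRESHOLD`` —
    the ranking is then of noise.
    """
    weights = np.abs(result.standardized_A2[:, 0])
    if result.correlations[0] < WEAK_CORRELATION_THRESHOLD:
        logger.warning(
            "first canonical correlation %.3f < %.2f; ranking is weakly supported",
            result.correlations[0],
            WEAK_CORRELATION_THRESHOLD,
        )
    order = sorted(range(len(weights)), key=lambda j: (-weights[j], j))
    return [(result.labels[j], float(weights[j])) for j in order]
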