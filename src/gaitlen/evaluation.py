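"""Error metrics for stride-length and walked-distance evaluation.

Treadmill evaluation is per stride: signed errors e_i = d_est,i - d_ref,i in
centimeters, summarized as MAE (mean |e|), SD (sample standard deviation of
|e|) and CV = SD / MAE, with over/underestimation shares and the same three
statistics within each subset.  Free-walking (polygon) evaluation is per
trial: the walked-distance error e = (d_est - d) / d * 100 %, summarized the
same way.

The SD is the standard deviation of the *absolute* errors: that convention,
with CV = SD/MAE, reproduces every published CV in the evaluation tables
this package mirrors, which is what fixes the otherwise-unstated definition.
A zero error counts as underestimation so the two shares always total 100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as report tables print."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ErrorSummary:
    """MAE / SD / CV triple with the count it was computed from.

    ``sd`` and ``cv`` are None when fewer than two errors are available —
    undefined is never reported as zero.
    """

    mae: float
    sd: float | None
    cv: float | None
    n: int


@dataclass
class EvalReport:
    """Full evaluation summary for one (model, position, speed) scope."""

    scope: dict[str, str]
    overall: ErrorSummary
    over: ErrorSummary | None
    under: ErrorSummary | None
    over_share: float  # percent of strides with e > 0
    under_share: float  # percent with e <= 0
    units: str = "cm"
    errors: np.ndarray = field(default_factory=lambda: np.array([]))


def stride_errors(est_lengths_m, ref_lengths_m) -> np.ndarray:
    """Signed per-stride errors (d_est - d_ref) in centimeters."""
    est = np.asarray(est_lengths_m, dtype=float)
    ref = np.asarray(ref_lengths_m, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} estimates vs {ref.shape} references")
    if est.size < 1:
        raise ValueError("need at least one stride")
    return (est - ref) * 100.0


def _summary(abs_errors: np.ndarray) -> ErrorSummary:
    n = int(abs_errors.size)
    mae = float(np.mean(abs_errors))
    if n < 2:
        return ErrorSummary(mae=mae, sd=None, cv=None, n=n)
    sd = float(np.std(abs_errors, ddof=1))
    cv = sd / mae if mae > 0 else None
    return ErrorSummary(mae=mae, sd=sd, cv=cv, n=n)


def summarize(errors, scope: dict[str, str] | None = None, units: str = "cm") -> EvalReport:
    """Summarize signed errors: overall, overestimation and underestimation.

    Overestimation is e > 0, underestimation e <= 0.  The over/under MAEs
    satisfy the exact weighted decomposition
    MAE_over * n_over + MAE_under * n_under = MAE_all * n.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 1:
        raise ValueError("need at least one error")
    over_mask = e > 0
    n = e.size
    over = _summary(np.abs(e[over_mask])) if over_mask.any() else None
    under = _summary(np.abs(e[~over_mask])) if (~over_mask).any() else None
    return EvalReport(
        scope=dict(scope or {}),
        overall=_summary(np.abs(e)),
        over=over,
        under=under,
        over_share=100.0 * over_mask.sum() / n,
        under_share=100.0 * (~over_mask).sum() / n,
        units=units,
        errors=e,
    )


def distance_error(d_est_m: float, d_m: float) -> float:
    """Signed walked-distance error in percent: (d_est - d) / d * 100."""
    if d_m <= 0:
        raise ValueError("measured distance must be positive")
    return (d_est_m - d_m) / d_m * 100.0


def polygon_summary(trial_errors_pct, scope: dict[str, str] | None = None) -> EvalReport:
    """Summarize per-trial walked-distance percentage errors."""
    return summarize(trial_errors_pct, scope=scope, units="%")


def report_table(reports: list[EvalReport]) -> "pd.DataFrame":
    """Aligned summary table (one row per report) for CSV/text output."""
    import pandas as pd

    rows = []
    for r in reports:
        row = dict(r.scope)
        row.update(
            {
                f"MAE [{r.units}]": round_half_up(r.overall.mae),
                f"SD [{r.units}]": None if r.overall.sd is None else round_half_up(r.overall.sd),
                "CV": None if r.overall.cv is None else round_half_up(r.overall.cv),
                "over_share [%]": round_half_up(r.over_share),
                "under_share [%]": round_half_up(r.under_share),
                "n": r.overall.n,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
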