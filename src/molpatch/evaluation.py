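"""Prediction-quality statistics: relative errors and threshold curves.

For a measure m on chain i, the relative error is

    delta_i = |m_pred,i - m_ref,i| / m_ref,i

and the threshold curve reports, for each error threshold t, the
percentage of chains predicted with delta strictly below t:

    F(t) = 100 * |{i : delta_i < t}| / |{i}|

F is robust to outliers (a GDT-style summary) and need not reach 100% at
t = 1 since relative errors can exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PredictionRecord:
    chain_id: str
    measure: str            # "THSA" | "RHSA" | "LHP"
    predicted: float
    reference: float


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray
    percent_correct: np.ndarray
    n_chains: int
    n_excluded: int


def relative_error(rec: PredictionRecord) -> float:
    """|predicted - reference| / reference; requires a positive reference."""
    if rec.reference <= 0:
        raise ValueError(f"non-positive reference for chain {rec.chain_id!r}")
    return abs(rec.predicted - rec.reference) / rec.reference


def default_grid(step: float = 0.01, stop: float = 1.0) -> np.ndarray:
    """Error-threshold grid from 0 to ``stop`` inclusive."""
    n = int(round(stop / step))
    return np.linspace(0.0, stop, n + 1)


def threshold_curve(
    records: Sequence[PredictionRecord], grid: np.ndarray | None = None
) -> ThresholdCurve:
    """Percentage of chains with relative error strictly below each threshold.

    Chains with zero reference value cannot have a relative error; they are
    excluded from both numerator and denominator and counted in
    ``n_excluded``.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    included = [r for r in records if r.reference > 0]
    n_excluded = len(records) - len(included)
    if not included:
        raise ValueError("no records with positive reference value")
    deltas = np.array([relative_error(r) for r in included])
    percent = np.array(
        [100.0 * np.count_nonzero(deltas < t) / len(deltas) for t in grid]
    )
    return ThresholdCurve(
        thresholds=grid,
        percent_correct=percent,
        n_chains=len(included),
        n_excluded=n_excluded,
    )


def r_squared(records: Sequence[PredictionRecord], kind: str = "pearson") -> float:
    """R^2 between predictions and references.

    ``pearson``  squared Pearson correlation (default).
    ``r2_score`` coefficient of determination, 1 - SS_res/SS_tot.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    pred = np.array([r.predicted for r in records])
    ref = np.array([r.reference for r in records])
    if np.ptp(ref) == 0:
        raise ValueError("constant reference values")
    if kind == "pearson":
        if np.ptp(pred) == 0:
            raise ValueError("constant predicted values")
        r, _ = stats.pearsonr(pred, ref)
        return float(r * r)
    if kind == "r2_score":
        ss_res = float(np.sum((ref - pred) ** 2))
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown kind {kind!r}")
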