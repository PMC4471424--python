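"""Classification and dose-error metrics, and model comparison tables.

Conventions: the positive class is the high-required-dose class (label 1);
``fp`` counts predicted-positive/actual-negative records. Precision is
reported with its standard definitions, ``precision_pos = TP/(TP+FP)`` and
``precision_neg = TN/(TN+FN)``. (Some published confusion-matrix layouts swap
the FP/FN cell names; under such a swapped layout the standard formulas
compute exactly the row-wise quantities those tables intend.) Undefined
ratios (zero denominator) are returned as NaN with a warning.

Dose errors are RMSE = sqrt(mean((actual - predicted)^2)) and
MAE = mean(|actual - predicted|), both in mg/wk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """Standard-orientation confusion counts (positive = class 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ComparisonRow:
    """One model's dose-error summary (mg/wk)."""

    model_name: str
    rmse: float
    mae: float

    def __post_init__(self) -> None:
        if not (self.rmse >= self.mae >= 0):
            raise ValidationError("rows must satisfy rmse >= mae >= 0")


def _as_binary(v, what: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{what} is empty")
    if set(np.unique(arr)) - {0.0, 1.0}:
        raise ValidationError(f"{what} must contain only 0/1 labels")
    return arr.astype(int)


def confusion(actual, predicted) -> ConfusionCounts:
    """Tabulate agreement between actual and predicted 0/1 labels."""
    a = _as_binary(actual, "actual")
    p = _as_binary(predicted, "predicted")
    if len(a) != len(p):
        raise ValidationError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    return ConfusionCounts(
        tp=int(np.sum((a == 1) & (p == 1))),
        fp=int(np.sum((a == 0) & (p == 1))),
        tn=int(np.sum((a == 0) & (p == 0))),
        fn=int(np.sum((a == 1) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return math.nan
    return num / den


def classification_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and both precisions from counts."""
    if cc.total == 0:
        raise ValidationError("cannot compute metrics on zero records")
    return {
        "accuracy": (cc.tp + cc.tn) / cc.total,
        "sensitivity": _ratio(cc.tp, cc.tp + cc.fn, "sensitivity"),
        "specificity": _ratio(cc.tn, cc.tn + cc.fp, "specificity"),
        "precision_pos": _ratio(cc.tp, cc.tp + cc.fp, "precision_pos"),
        "precision_neg": _ratio(cc.tn, cc.tn + cc.fn, "precision_neg"),
    }


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size == 0:
        raise ValidationError("empty dose vectors")
    if a.size != p.size:
        raise ValidationError(f"length mismatch: {a.size} actual vs {p.size} predicted")
    return a, p


def rmse(actual, predicted) -> float:
    """Root mean squared dose error (mg/wk)."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mae(actual, predicted) -> float:
    """Mean absolute dose error (mg/wk)."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def improvement_pct(baseline: float, proposed: float) -> tuple[int, float]:
    """Percent error reduction of ``proposed`` relative to ``baseline``.

    Returns ``(rounded, raw)`` where ``raw = 100 * (baseline - proposed) /
    baseline`` and ``rounded`` is the nearest integer percent under
    round-half-up (the convention used when reporting).
    """
    if not baseline > 0:
        raise ValidationError("baseline must be strictly positive")
    raw = 100.0 * (baseline - proposed) / baseline
    rounded = int(math.floor(raw + 0.5))
    return rounded, raw


def comparison_table(actual, predictions: dict[str, np.ndarray]) -> list[ComparisonRow]:
    """One row of RMSE/MAE per model, sorted by RMSE ascending."""
    a = np.asarray(actual, dtype=float).ravel()
    rows = []
    for name, pred in predictions.items():
        p = np.asarray(pred, dtype=float).ravel()
        if p.size != a.size:
            raise ValidationError(
                f"model {name!r}: prediction length {p.size} != actual length {a.size}"
            )
        rows.append(ComparisonRow(name, rmse(a, p), mae(a, p)))
    return sorted(rows, key=lambda r: r.rmse)


def comparison_frame(rows: list[ComparisonRow], baseline: str | None = None) -> pd.DataFrame:
    """Tabulate comparison rows; optionally add percent RMSE/MAE improvement
    of every model relative to the named baseline row."""
    df = pd.DataFrame([{"model": r.model_name, "rmse": r.rmse, "mae": r.mae} for r in rows])
    if baseline is not None:
        base = {r.model_name: r for r in rows}.get(baseline)
        if base is None:
            raise ValidationError(f"baseline model {baseline!r} not among rows")
        df["rmse_improvement_pct"] = [
            improvement_pct(base.rmse, r.rmse)[0] if base.rmse > 0 else 0 for r in rows
        ]
        df["mae_improvement_pct"] = [
            improvement_pct(base.mae, r.mae)[0] if base.mae > 0 else 0 for r in rows
        ]
    return df
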