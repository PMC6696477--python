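"""Assessment metrics and the RPD category taxonomy.

The pipeline judges calibration and prediction quality with:

* ``RMSE = sqrt(sum((yhat - y)^2) / m)``;
* ``MSECV`` — mean squared error of out-of-fold cross-validated
  predictions; ``RMSECV`` is its square root;
* two coefficients of determination: the squared Pearson correlation
  between predictions and observations (``r2_corr``), and the training
  form ``r2_train`` with a "printed" variant whose denominator centres
  the *predictions* on the observed mean
  (``1 - sum((yhat-y)^2) / sum((yhat - mean(y))^2)``) alongside the
  conventional ``1 - sum((yhat-y)^2) / sum((y - mean(y))^2)``;
* ``RPD = SD(y) / RMSE = sqrt(sum((y-ybar)^2) / sum((f-y)^2))`` with the
  population-n factors cancelling, and its soil-property taxonomy:
  type A (RPD >= 2.0, high prediction ability), type B (1.4 <= RPD < 2.0,
  moderate), type C (RPD < 1.4, weak).

Boundary RPD values are assigned upward (2.0 -> A, 1.4 -> B); an exact
prediction yields an infinite RPD flag, classified A.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import LengthError, ModelCompatibilityError, ParameterError

__all__ = [
    "rmse", "msecv", "rmsecv", "r2_train", "r2_corr", "rpd",
    "classify_rpd", "evaluate", "EvaluationReport", "PERFECT_PREDICTION",
]

#: Flag value returned by :func:`rpd` when the residuals are exactly zero.
PERFECT_PREDICTION = math.inf


def _pair(pred, obs, min_len=1):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise LengthError(
            f"prediction/observation length mismatch: {pred.size} vs {obs.size}"
        )
    if pred.size < min_len:
        raise LengthError(f"need at least {min_len} value(s)")
    return pred, obs


def rmse(pred, obs) -> float:
    """Root mean square error ``sqrt(sum((yhat - y)^2) / m)``."""
    pred, obs = _pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def msecv(fold_predictions, obs) -> float:
    """Mean squared error of cross-validated (out-of-fold) predictions."""
    pred, obs = _pair(fold_predictions, obs)
    return float(np.mean((pred - obs) ** 2))


def rmsecv(loo_predictions, obs) -> float:
    """Root mean square error of leave-one-out predictions."""
    return float(math.sqrt(msecv(loo_predictions, obs)))


def r2_train(pred, obs, form: str = "printed") -> float:
    """Training-set coefficient of determination.

    ``form="printed"`` uses ``1 - SSE / sum((yhat - mean(y))^2)`` — the
    denominator centres the predictions on the observed mean.  The
    conventional form ``1 - SSE / sum((y - mean(y))^2)`` is available as
    ``form="conventional"``.  Unlike the conventional form, the printed
    form is not invariant under affine transformation of predictions.
    """
    if form not in ("printed", "conventional"):
        raise ParameterError(f"unknown form {form!r}")
    pred, obs = _pair(pred, obs, min_len=2)
    ybar = obs.mean()
    sse = np.sum((pred - obs) ** 2)
    denom = np.sum((pred - ybar) ** 2) if form == "printed" \
        else np.sum((obs - ybar) ** 2)
    if denom == 0:
        raise ParameterError("degenerate target: zero denominator")
    return float(1.0 - sse / denom)


def r2_corr(pred, obs) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred, obs = _pair(pred, obs, min_len=2)
    cp = pred - pred.mean()
    co = obs - obs.mean()
    denom = np.sum(cp ** 2) * np.sum(co ** 2)
    if denom == 0:
        raise ParameterError("undefined correlation: constant input")
    return float(np.sum(cp * co) ** 2 / denom)


def rpd(pred, obs) -> float:
    """Ratio of performance to deviation, ``sqrt(sum((y-ybar)^2)/sum((f-y)^2))``.

    Returns :data:`PERFECT_PREDICTION` (infinity) when the residual sum
    is exactly zero, rather than raising.
    """
    pred, obs = _pair(pred, obs, min_len=2)
    ss_dev = np.sum((obs - obs.mean()) ** 2)
    if ss_dev == 0:
        raise ParameterError("constant observations: zero SD")
    ss_res = np.sum((pred - obs) ** 2)
    if ss_res == 0:
        return PERFECT_PREDICTION
    return float(math.sqrt(ss_dev / ss_res))


def classify_rpd(value: float) -> str:
    """RPD category for soil-property prediction: A / B / C.

    A: RPD >= 2.0 (high prediction ability); B: 1.4 <= RPD < 2.0
    (moderate); C: RPD < 1.4 (weak).  The perfect-prediction flag
    (infinity) maps to A.
    """
    if value != value or value < 0:  # NaN or negative
        raise ParameterError(f"RPD must be non-negative, got {value}")
    if value >= 2.0:
        return "A"
    if value >= 1.4:
        return "B"
    return "C"


@dataclass
class EvaluationReport:
    """Metrics of one model on one dataset (calibration or prediction phase)."""

    phase: str
    n: int
    r2: float
    rmse: float
    rpd: float
    category: str
    r2_train: float | None = None
    model_kind: str | None = None

    def to_dict(self) -> dict:
        d = {"phase": self.phase, "n": self.n, "r2": self.r2,
             "rmse": self.rmse, "rpd": self.rpd, "category": self.category}
        if self.r2_train is not None:
            d["r2_train"] = self.r2_train
        if self.model_kind is not None:
            d["model"] = self.model_kind
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            f"{self.model_kind or 'model'} — {self.phase} (n = {self.n})",
            f"  R^2   : {self.r2:.3f}",
            f"  RMSE  : {self.rmse:.3f}",
            f"  RPD   : {self.rpd:.3f}  (type {self.category})",
        ]
        if self.r2_train is not None:
            lines.insert(2, f"  R^2_T : {self.r2_train:.3f}")
        return "\n".join(lines)


def evaluate(model, data, phase: str = "prediction") -> EvaluationReport:
    """Predict a dataset with a fitted calibrator and assemble a report.

    Parameters
    ----------
    model : fitted calibration result
        Anything with ``predict(X)`` and ``kind``; feature width must
        match the training width.
    data : Dataset
        Feature matrix with reference SOM values.
    phase : "calibration" or "prediction"
        Calibration reports additionally carry the training-form R^2.
    """
    if phase not in ("calibration", "prediction"):
        raise ParameterError(f"unknown phase {phase!r}")
    n_model = getattr(model, "n_features", None)
    if n_model is not None and data.X.shape[1] != n_model:
        raise ModelCompatibilityError(
            f"model expects {n_model} features, data has {data.X.shape[1]}"
        )
    pred = np.asarray(model.predict(data.X), dtype=float).ravel()
    value = rpd(pred, data.y)
    return EvaluationReport(
        phase=phase,
        n=len(data.y),
        r2=r2_corr(pred, data.y),
        rmse=rmse(pred, data.y),
        rpd=value,
        category=classify_rpd(value),
        r2_train=r2_train(pred, data.y) if phase == "calibration" else None,
        model_kind=getattr(model, "kind", None),
    )
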