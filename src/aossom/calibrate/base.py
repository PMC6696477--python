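"""Shared containers for the calibration models.

The calibrators follow a model/results split: a model object is built
from a :class:`Dataset` (feature matrix paired with reference SOM
values), ``fit()`` performs the model-selection protocol and returns a
:class:`CalibrationResult` carrying the fitted predictor, the selected
hyperparameters and the selection diagnostics, with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import LengthError, ModelCompatibilityError, ParameterError

__all__ = ["Dataset", "CalibrationResult"]


@dataclass
class Dataset:
    """Feature matrix paired with reference SOM values (g/kg).

    Attributes
    ----------
    X : ndarray (n_samples, n_features)
        Normalised olfactory features (40 columns in the standard
        pipeline).
    y : ndarray (n_samples,)
        Reference SOM contents, g/kg.
    sample_ids : tuple
        Unique sample identifiers, aligned with the rows.
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: tuple = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ParameterError("X must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise LengthError(
                f"X has {self.X.shape[0]} rows but y has {self.y.size}"
            )
        if self.sample_ids is None:
            self.sample_ids = tuple(range(self.X.shape[0]))
        else:
            self.sample_ids = tuple(self.sample_ids)
        if len(self.sample_ids) != self.X.shape[0]:
            raise LengthError("sample_ids length must match rows")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ParameterError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       target: str = "som_g_per_kg") -> "Dataset":
        """Build from a feature table with the target as a named column."""
        if target not in frame.columns:
            raise ParameterError(f"target column {target!r} not in frame")
        X = frame.drop(columns=[target])
        return cls(X=X.to_numpy(dtype=float),
                   y=frame[target].to_numpy(dtype=float),
                   sample_ids=tuple(frame.index))

    def subset(self, ids) -> "Dataset":
        """Row subset by sample id, in the given id order."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            rows = [index[sid] for sid in ids]
        except KeyError as exc:
            raise ParameterError(f"unknown sample id {exc.args[0]!r}") from None
        return Dataset(X=self.X[rows], y=self.y[rows],
                       sample_ids=tuple(ids))


class CalibrationResult:
    """A fitted calibrator: deterministic predictor plus selection metadata.

    Attributes
    ----------
    kind : str
        ``"bpnn"``, ``"svr"`` or ``"plsr"``.
    hyperparams : dict
        Selected hyperparameters (hidden size h; C and sigma^2; factor
        count).
    selection : object or None
        The full selection diagnostics (a DataFrame table, grid-search
        surfaces, or RMSECV/AIC curves).
    """

    def __init__(self, kind: str, predict_fn, n_features: int,
                 hyperparams: dict, selection=None, extra: dict | None = None):
        self.kind = kind
        self._predict_fn = predict_fn
        self.n_features = int(n_features)
        self.hyperparams = dict(hyperparams)
        self.selection = selection
        self.extra = dict(extra or {})

    def predict(self, X) -> np.ndarray:
        """Predict SOM (g/kg) for a feature matrix of matching width."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ModelCompatibilityError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        return np.asarray(self._predict_fn(X), dtype=float).ravel()

    def summary(self) -> str:
        lines = [f"Calibration model: {self.kind}",
                 f"  features: {self.n_features}"]
        for key, value in self.hyperparams.items():
            lines.append(f"  {key}: {value}")
        for key, value in self.extra.items():
            lines.append(f"  {key}: {value}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in self.hyperparams.items())
        return f"<CalibrationResult {self.kind} ({hp})>"
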