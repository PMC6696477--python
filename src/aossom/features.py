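"""Transient features of sensor response curves and the 40-D feature space.

Four features summarise each sensor's response curve:

* ``Vmax`` — maximum voltage over the acquisition window (V);
* ``MDCV`` — mean differential coefficient value, the average slope
  ``(1/(N-1)) * sum((D[i+1]-D[i])/dt)`` (V/s), which telescopes to
  ``(D_N - D_1) / ((N-1)*dt)``;
* ``RAV`` — response area value, the left-rectangle sum
  ``sum(D_i * dt)`` (V*s);
* ``Vt`` — the transient value at a fixed time, t = 20 s by default (V).

With 10 sensors this gives a 40-dimensional vector per soil sample.  To
remove order-of-magnitude and overall gas-concentration effects, each
feature type is normalised across the 10 sensors within a sample:
``Xnew(i) = (X(i) - u(x)) / S(x)`` with ``u(x)`` the cross-sensor mean
and ``S(x)`` the cross-sensor n-1 variance.  The variance (not its
square root) is the divisor in the as-printed convention; an ``sd``
normaliser is available for the conventional z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (DegenerateFeatureError, LengthError, ParameterError)
from .signal_io import N_SENSORS, SensorRecording

__all__ = [
    "FEATURE_NAMES",
    "RawFeatureTable",
    "vmax",
    "mdcv",
    "rav",
    "vt",
    "extract_features",
    "normalize_features",
    "feature_names_40",
]

FEATURE_NAMES = ("Vmax", "MDCV", "RAV", "Vt")


def vmax(series) -> float:
    """Maximum voltage over the window."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise LengthError("series must be non-empty")
    return float(series.max())


def mdcv(series, dt: float) -> float:
    """Mean differential coefficient value: average first difference / dt.

    Equals ``(D_N - D_1) / ((N - 1) * dt)`` by telescoping.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise LengthError("series must have at least 2 samples")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    diffs = np.diff(series) / dt
    return float(diffs.mean())


def rav(series, dt: float) -> float:
    """Response area value: left-rectangle sum of the curve, ``sum(D_i)*dt``."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise LengthError("series must be non-empty")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    return float(series.sum() * dt)


def vt(series, t_target: float = 20.0, dt: float = 0.1) -> float:
    """Transient value at ``t_target`` seconds.

    Under the convention that sample ``i`` (1-based) sits at
    ``t = (i - 1) * dt``, this is the sample at index
    ``t_target / dt + 1`` (sample 201 for t = 20 s at 10 Hz).
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0:
        raise ParameterError("dt must be positive")
    pos = t_target / dt
    idx = int(round(pos))
    if abs(pos - idx) > 1e-6:
        raise IndexError(
            f"t = {t_target} s is not on the sampling grid (dt = {dt} s)"
        )
    if idx < 0 or idx >= series.size:
        raise IndexError(
            f"t = {t_target} s (sample {idx + 1}) beyond the recorded window"
        )
    return float(series[idx])


@dataclass
class RawFeatureTable:
    """Unnormalised per-sensor features for one sample: a 10 x 4 array.

    Rows are sensors S1..S10; columns are Vmax (V), MDCV (V/s),
    RAV (V*s), Vt (V).  No ordering between Vmax and Vt is assumed.
    """

    sample_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SENSORS, len(FEATURE_NAMES)):
            raise ParameterError(
                f"expected shape {(N_SENSORS, len(FEATURE_NAMES))}, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ParameterError("features must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=list(FEATURE_NAMES),
            index=[f"S{k}" for k in range(1, N_SENSORS + 1)],
        )


def extract_features(recording: SensorRecording,
                     t_target: float = 20.0) -> RawFeatureTable:
    """Extract the four transient features from each of the 10 channels."""
    rows = []
    for k, channel in enumerate(recording.channels, start=1):
        try:
            rows.append([
                vmax(channel),
                mdcv(channel, recording.dt),
                rav(channel, recording.dt),
                vt(channel, t_target, recording.dt),
            ])
        except (LengthError, ParameterError, IndexError) as exc:
            raise type(exc)(f"channel S{k}: {exc}") from exc
    return RawFeatureTable(sample_id=recording.sample_id,
                           values=np.asarray(rows))


def feature_names_40() -> list[str]:
    """Column names of the sensor-major 40-vector: S1_Vmax, S1_MDCV, ..., S10_Vt."""
    return [f"S{k}_{name}" for k in range(1, N_SENSORS + 1)
            for name in FEATURE_NAMES]


def normalize_features(raw: RawFeatureTable,
                       normalizer: str = "variance") -> np.ndarray:
    """Cross-sensor normalisation producing the 40-vector for one sample.

    For each feature type independently: subtract the mean over the 10
    sensors and divide by the n-1 variance over the 10 sensors (the
    as-printed convention, ``normalizer="variance"``) or by its square
    root (``normalizer="sd"``).  The output is assembled sensor-major:
    (S1:Vmax, S1:MDCV, S1:RAV, S1:Vt, S2:Vmax, ...).

    Raises
    ------
    DegenerateFeatureError
        If all 10 sensors agree on some feature type (zero variance).
    """
    if normalizer not in ("variance", "sd"):
        raise ParameterError(f"unknown normalizer {normalizer!r}")
    X = raw.values  # (10 sensors, 4 feature types)
    u = X.mean(axis=0)
    S = np.sum((X - u) ** 2, axis=0) / (N_SENSORS - 1)
    for j, name in enumerate(FEATURE_NAMES):
        if S[j] == 0.0:
            raise DegenerateFeatureError(
                f"feature {name} is identical across all sensors"
            )
    divisor = S if normalizer == "variance" else np.sqrt(S)
    normalized = (X - u) / divisor
    return normalized.reshape(-1)  # sensor-major: rows are sensors


def features_to_frame(tables, normalizer: str = "variance",
                      som=None) -> pd.DataFrame:
    """Assemble normalised feature vectors into a sample-by-feature table.

    Parameters
    ----------
    tables : iterable of RawFeatureTable
    normalizer : "variance" or "sd"
    som : optional sequence of reference SOM values (g/kg), appended as a
        ``som_g_per_kg`` column.
    """
    tables = list(tables)
    data = np.stack([normalize_features(t, normalizer) for t in tables])
    frame = pd.DataFrame(data, columns=feature_names_40(),
                         index=pd.Index([t.sample_id for t in tables],
                                        name="sample_id"))
    if som is not None:
        som = np.asarray(som, dtype=float)
        if som.size != len(tables):
            raise ParameterError("som length must match number of samples")
        frame["som_g_per_kg"] = som
    return frame
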