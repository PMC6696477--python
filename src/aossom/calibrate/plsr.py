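"""Partial least squares regression calibrator with LOO factor selection.

PLSR regresses the response on latent factors — covariance-maximising
linear combinations of the (centred, scaled) predictors extracted by
iterative NIPALS deflation — instead of on the raw 40 features, which
tames their collinearity.  The number of retained factors ``p`` is
chosen by leave-one-out cross-validation: for each candidate ``p`` the
LOO residuals give RMSECV and the Akaike information criterion
``AIC = N * ln(RSS) + 2p`` (natural log, RSS the sum of squared LOO
residuals); the ``p`` minimising AIC wins, ties to the smaller ``p``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from ..exceptions import (DegenerateInputError, LengthError, ParameterError)
from ..evaluation import rmsecv as _rmsecv
from .base import CalibrationResult, Dataset

__all__ = ["PLSRConfig", "PLSRModel", "fit_plsr", "select_pcfs", "aic"]


def aic(n: int, rss: float, p: int) -> float:
    """Akaike information criterion ``N * ln(RSS) + 2p`` (natural log)."""
    if rss <= 0:
        raise ParameterError("RSS must be > 0 for the log")
    return float(n * math.log(rss) + 2 * p)


@dataclass
class PLSRConfig:
    """Factor-selection settings: candidate cap and (AIC) selection rule."""

    max_factors: int = 15

    def __post_init__(self):
        if self.max_factors < 1:
            raise ParameterError("max_factors must be >= 1")


def _check_columns(X):
    if np.any(X.std(axis=0, ddof=0) == 0):
        bad = np.flatnonzero(X.std(axis=0, ddof=0) == 0)
        raise DegenerateInputError(
            f"zero-variance predictor column(s): {bad.tolist()}"
        )


def _fit_sklearn(X, y, p):
    with warnings.catch_warnings():
        # deflation may exhaust the response space before p components
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=p, scale=True)
        model.fit(X, y)
    return model


class PLSRModel:
    """PLSR calibrator: NIPALS latent factors, LOO/AIC factor count."""

    def __init__(self, train: Dataset, config: PLSRConfig | None = None):
        if len(train) < 3:
            raise LengthError("need at least 3 training samples")
        self.train = train
        self.config = config or PLSRConfig()

    def _candidate_cap(self) -> int:
        n, k = self.train.X.shape
        cap = min(self.config.max_factors, n - 1, k)
        rank = int(np.linalg.matrix_rank(self.train.X - self.train.X.mean(0)))
        if cap > rank:
            warnings.warn(
                f"max_factors truncated from {cap} to matrix rank {rank}"
            )
            cap = rank
        return max(1, cap)

    def select_factors(self):
        """LOO selection; returns ``(p, curve DataFrame)``.

        The curve has one row per candidate factor count with its
        RMSECV and AIC.
        """
        X, y = self.train.X, self.train.y
        _check_columns(X)
        n = len(y)
        cap = self._candidate_cap()
        loo_pred = np.empty((cap, n))
        for i in range(n):
            mask = np.arange(n) != i
            for p in range(1, cap + 1):
                model = _fit_sklearn(X[mask], y[mask], p)
                loo_pred[p - 1, i] = model.predict(X[[i]]).ravel()[0]
        rows = []
        for p in range(1, cap + 1):
            resid = loo_pred[p - 1] - y
            rss = float(np.sum(resid ** 2))
            rows.append({
                "p": p,
                "rmsecv": _rmsecv(loo_pred[p - 1], y),
                "aic": aic(n, rss, p) if rss > 0 else -math.inf,
            })
        curve = pd.DataFrame(rows)
        best = curve.sort_values(by=["aic", "p"], kind="mergesort").iloc[0]
        return int(best["p"]), curve

    def fit(self, n_factors: int | None = None) -> CalibrationResult:
        """Select (or accept) the factor count and fit the final model."""
        curve = None
        if n_factors is None:
            n_factors, curve = self.select_factors()
        n, k = self.train.X.shape
        if not 1 <= n_factors <= min(n - 1, k):
            raise ParameterError(
                f"n_factors must be in [1, {min(n - 1, k)}], got {n_factors}"
            )
        _check_columns(self.train.X)
        model = _fit_sklearn(self.train.X, self.train.y, n_factors)
        return CalibrationResult(
            kind="plsr",
            predict_fn=lambda X: model.predict(X).ravel(),
            n_features=self.train.n_features,
            hyperparams={"n_factors": int(n_factors)},
            selection=curve,
            extra={"algorithm": "NIPALS (centred, unit-variance scaled)"},
        )


def fit_plsr(train: Dataset, n_factors: int) -> CalibrationResult:
    """Fit a PLSR with a fixed number of latent factors."""
    return PLSRModel(train).fit(n_factors=n_factors)


def select_pcfs(train: Dataset, config: PLSRConfig | None = None):
    """LOO factor selection; returns ``(p, rmsecv curve, aic curve)``."""
    p, curve = PLSRModel(train, config).select_factors()
    return p, curve[["p", "rmsecv"]], curve[["p", "aic"]]
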