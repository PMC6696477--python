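"""ε-SVR calibrator with the two-stage log2 grid search.

Support-vector regression with the radial basis function kernel
``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))`` has two governing
hyperparameters: the penalty C and the kernel width sigma^2.  Both are
searched on powers of two in [2^-20, 2^20] in two stages:

1. a coarse grid (step 2 in log2) scored by the mean squared error of
   five-fold cross-validation (MSECV) with seeded, fixed fold
   assignment;
2. a fine grid (step 0.25 in log2) on a window around the coarse
   optimum (±5 log2 units by default, clipped to the coarse range),
   scored the same way.

Because the fine grid contains the coarse optimum and folds are
identical across cells, the refined optimum never scores worse than the
coarse one.  The ε tube width is left at the LIBSVM default (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from ..exceptions import LengthError, ParameterError
from ..evaluation import msecv as _msecv
from .base import CalibrationResult, Dataset

__all__ = ["SVRConfig", "SVRModel", "grid_search_svr", "train_svr"]


@dataclass
class SVRConfig:
    """Grid-search settings for the ε-SVR calibrator.

    ``coarse_range`` bounds the log2 exponents of both C and sigma^2;
    ``coarse_step`` / ``fine_step`` are the log2 grid steps of the two
    stages; ``fine_halfwidth`` is the half-width (log2 units) of the
    refinement window around the coarse optimum.  ``epsilon`` is the
    ε-insensitive tube width (LIBSVM default 0.1).
    """

    coarse_range: tuple = (-20, 20)
    coarse_step: float = 2.0
    fine_step: float = 0.25
    fine_halfwidth: float = 5.0
    folds: int = 5
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.coarse_range
        if lo > hi:
            raise ParameterError("empty coarse range")
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise ParameterError("grid steps must be > 0")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be >= 0")


def _fold_indices(n: int, config: SVRConfig):
    if n < config.folds:
        raise ParameterError(
            f"{config.folds}-fold CV needs at least {config.folds} samples"
        )
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    return list(kf.split(np.arange(n)))


def _mse_cv(X, y, C, sigma2, epsilon, folds):
    """MSECV at one grid cell: out-of-fold predictions for every sample."""
    pred = np.empty_like(y)
    gamma = 1.0 / (2.0 * sigma2)
    for train_idx, test_idx in folds:
        model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
        model.fit(X[train_idx], y[train_idx])
        pred[test_idx] = model.predict(X[test_idx])
    return _msecv(pred, y)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _search_surface(X, y, log2c_grid, log2s_grid, epsilon, folds):
    surface = np.empty((len(log2c_grid), len(log2s_grid)))
    for i, lc in enumerate(log2c_grid):
        for j, ls in enumerate(log2s_grid):
            surface[i, j] = _mse_cv(X, y, 2.0 ** lc, 2.0 ** ls,
                                    epsilon, folds)
    return pd.DataFrame(surface, index=pd.Index(log2c_grid, name="log2_C"),
                        columns=pd.Index(log2s_grid, name="log2_sigma2"))


def _argmin_cell(surface: pd.DataFrame):
    # np.argmin is row-major: ties resolve to the smallest (log2C, log2s2)
    flat = int(np.argmin(surface.to_numpy()))
    i, j = divmod(flat, surface.shape[1])
    return float(surface.index[i]), float(surface.columns[j])


class SVRModel:
    """ε-SVR calibrator with two-stage grid-searched (C, sigma^2)."""

    def __init__(self, train: Dataset, config: SVRConfig | None = None):
        if len(train) < 2:
            raise LengthError("need at least 2 training samples")
        self.train = train
        self.config = config or SVRConfig()

    def grid_search(self):
        """Run both stages; return ``(C, sigma2, surfaces dict)``.

        The surfaces (coarse and fine MSECV grids, log2 axes) are kept
        for contour plotting and diagnostics.
        """
        cfg = self.config
        X, y = self.train.X, self.train.y
        folds = _fold_indices(len(y), cfg)

        lo, hi = cfg.coarse_range
        coarse_axis = _grid(lo, hi, cfg.coarse_step)
        coarse = _search_surface(X, y, coarse_axis, coarse_axis,
                                 cfg.epsilon, folds)
        lc0, ls0 = _argmin_cell(coarse)

        fine_c = _grid(max(lo, lc0 - cfg.fine_halfwidth),
                       min(hi, lc0 + cfg.fine_halfwidth), cfg.fine_step)
        fine_s = _grid(max(lo, ls0 - cfg.fine_halfwidth),
                       min(hi, ls0 + cfg.fine_halfwidth), cfg.fine_step)
        fine = _search_surface(X, y, fine_c, fine_s, cfg.epsilon, folds)
        lc1, ls1 = _argmin_cell(fine)

        surfaces = {"coarse": coarse, "fine": fine,
                    "coarse_opt": (lc0, ls0), "fine_opt": (lc1, ls1)}
        return 2.0 ** lc1, 2.0 ** ls1, surfaces

    def fit(self, C: float | None = None,
            sigma2: float | None = None) -> CalibrationResult:
        """Grid-search (C, sigma^2) unless both are forced; train the SVR."""
        surfaces = None
        if C is None or sigma2 is None:
            C, sigma2, surfaces = self.grid_search()
        result = train_svr(self.train, C, sigma2, self.config)
        result.selection = surfaces
        return result


def train_svr(train: Dataset, C: float, sigma2: float,
              config: SVRConfig | None = None) -> CalibrationResult:
    """Fit one ε-SVR with RBF kernel ``exp(-||u-v||^2 / (2 sigma^2))``."""
    config = config or SVRConfig()
    if C <= 0 or sigma2 <= 0:
        raise ParameterError("C and sigma^2 must be > 0")
    gamma = 1.0 / (2.0 * sigma2)
    model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=config.epsilon)
    model.fit(train.X, train.y)
    return CalibrationResult(
        kind="svr",
        predict_fn=model.predict,
        n_features=train.n_features,
        hyperparams={"C": float(C), "sigma2": float(sigma2)},
        extra={"kernel": "rbf: exp(-||u-v||^2 / (2*sigma2)), "
                         f"gamma = 1/(2*sigma2) = {gamma:.6g}",
               "epsilon": config.epsilon},
    )


def grid_search_svr(train: Dataset, config: SVRConfig | None = None):
    """Two-stage MSECV grid search; returns ``(C, sigma2, surfaces)``."""
    return SVRModel(train, config).grid_search()
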