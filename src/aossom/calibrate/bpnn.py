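"""Back-propagation neural network calibrator with hidden-size selection.

The network is the classic single-hidden-layer regressor: ``n_in - h - 1``
with hyperbolic-tangent-sigmoid hidden units and a linear output, trained
by gradient back-propagation (full-batch Adam) on standardised inputs and
targets until the training mean-squared error reaches the target error or
the iteration budget is exhausted.

The hidden size ``h`` is chosen by the repeat-and-average protocol: every
candidate ``h`` is trained ``repeats`` times from different seeded
initialisations; the per-candidate min/max/mean of the training-set R^2
and RMSE are tabulated, and the ``h`` with the largest mean R^2 wins
(ties: smaller mean RMSE, then smaller h).  The candidate range follows
the empirical rule ``h = round(sqrt(n_in + n_out)) + alpha`` with alpha
in 1..10, overridable; the 40-input / 1-output default override is
[6, 16].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import (LengthError, ParameterError,
                          TrainingDivergenceError)
from ..evaluation import r2_train as _r2_train, rmse as _rmse
from .base import CalibrationResult, Dataset

__all__ = [
    "BPNNConfig", "BPNNModel", "hidden_range_from_rule",
    "train_bpnn", "select_hidden_size", "select_hidden_from_table",
]


@dataclass
class BPNNConfig:
    """Training and selection settings for the BPNN calibrator.

    ``hidden_range`` is the inclusive candidate interval for the hidden
    size; ``repeats`` re-trainings per candidate feed the selection
    table; ``max_iterations``, ``learning_rate`` and ``target_error``
    (an MSE threshold on standardised targets) govern each training run.
    """

    hidden_range: tuple = (6, 16)
    repeats: int = 10
    max_iterations: int = 1000
    learning_rate: float = 0.01
    target_error: float = 0.001
    seed: int = 0
    r2_form: str = "printed"

    def __post_init__(self):
        lo, hi = self.hidden_range
        if not (1 <= lo <= hi <= 100):
            raise ParameterError("hidden_range must lie within [1, 100]")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")
        if self.max_iterations < 1 or self.learning_rate <= 0:
            raise ParameterError("bad training settings")
        if self.target_error <= 0:
            raise ParameterError("target_error must be > 0")


def hidden_range_from_rule(n_inputs: int, n_outputs: int = 1,
                           alpha_range: tuple = (1, 10),
                           override: tuple | None = None) -> list[int]:
    """Candidate hidden sizes from the rule ``round(sqrt(n + p)) + alpha``.

    ``alpha`` runs over the inclusive ``alpha_range``.  When ``override``
    is given it replaces the rule range outright — the 40-feature SOM
    experiment used [6, 16] even though the rule gives 7..16.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ParameterError("n_inputs and n_outputs must be >= 1")
    if override is not None:
        lo, hi = int(override[0]), int(override[1])
        if lo > hi:
            raise ParameterError("empty override range")
        return list(range(lo, hi + 1))
    a_lo, a_hi = int(alpha_range[0]), int(alpha_range[1])
    if a_lo > a_hi:
        raise ParameterError("empty alpha range")
    base = round(math.sqrt(n_inputs + n_outputs))
    candidates = sorted({base + a for a in range(a_lo, a_hi + 1)})
    candidates = [h for h in candidates if h >= 1]
    if not candidates:
        raise ParameterError("rule produced no positive candidates")
    return candidates


class _Network:
    """Weights of a n_in - h - 1 tanh network on standardised data."""

    def __init__(self, W1, b1, W2, b2, x_mean, x_sd, y_mean, y_sd):
        self.W1, self.b1, self.W2, self.b2 = W1, b1, W2, b2
        self.x_mean, self.x_sd = x_mean, x_sd
        self.y_mean, self.y_sd = y_mean, y_sd

    def forward(self, Xs):
        hidden = np.tanh(Xs @ self.W1 + self.b1)
        return hidden @ self.W2 + self.b2

    def predict(self, X):
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_sd
        return (self.forward(Xs).ravel() * self.y_sd) + self.y_mean


def _train_network(X, y, h, config: BPNNConfig, seed: int) -> _Network:
    rng = np.random.default_rng(seed)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0)) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = ((y - y_mean) / y_sd)[:, None]

    n_in = X.shape[1]
    W1 = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_in, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, 1.0 / math.sqrt(h), size=(h, 1))
    b2 = np.zeros(1)
    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    n = Xs.shape[0]

    for step in range(1, config.max_iterations + 1):
        hidden = np.tanh(Xs @ W1 + b1)
        out = hidden @ W2 + b2
        err = out - ys
        loss = float(np.mean(err ** 2))
        if not math.isfinite(loss):
            raise TrainingDivergenceError(
                f"non-finite training loss at iteration {step}"
            )
        if loss <= config.target_error:
            break
        g_out = 2.0 * err / n
        grads = [
            Xs.T @ ((g_out @ W2.T) * (1 - hidden ** 2)),
            np.sum((g_out @ W2.T) * (1 - hidden ** 2), axis=0),
            hidden.T @ g_out,
            np.sum(g_out, axis=0),
        ]
        for k, (p, g) in enumerate(zip(params, grads)):
            m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
            v_t[k] = beta2 * v_t[k] + (1 - beta2) * g ** 2
            m_hat = m_t[k] / (1 - beta1 ** step)
            v_hat = v_t[k] / (1 - beta2 ** step)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    return _Network(W1, b1, W2, b2, x_mean, x_sd, y_mean, y_sd)


def select_hidden_from_table(table: pd.DataFrame,
                             r2_col: str = "r2_mean",
                             rmse_col: str = "rmse_mean",
                             h_col: str = "h") -> int:
    """Apply the selection rule to a candidate table.

    Pick the hidden size with the largest mean training R^2; break ties
    by smaller mean training RMSE, then by smaller h.  Works equally on
    a freshly computed table or on a published selection grid.
    """
    if table.empty:
        raise LengthError("empty selection table")
    ranked = table.sort_values(
        by=[r2_col, rmse_col, h_col], ascending=[False, True, True],
        kind="mergesort",
    )
    return int(ranked.iloc[0][h_col])


class BPNNModel:
    """Single-hidden-layer back-propagation network for SOM calibration.

    Build from a training :class:`Dataset`; ``fit()`` runs the
    repeat-and-average hidden-size selection (unless ``h`` is forced)
    and returns a :class:`CalibrationResult` whose ``selection``
    attribute is the per-candidate min/max/mean table.
    """

    def __init__(self, train: Dataset, config: BPNNConfig | None = None):
        if len(train) < 2:
            raise LengthError("need at least 2 training samples")
        self.train = train
        self.config = config or BPNNConfig()

    def _repeat_seeds(self, h: int):
        ss = np.random.SeedSequence(entropy=self.config.seed, spawn_key=(h,))
        return [int(s % (2**31)) for s in
                ss.generate_state(self.config.repeats, dtype=np.uint64)]

    def selection_table(self, candidates=None) -> pd.DataFrame:
        """Train every candidate ``repeats`` times; tabulate R^2_T / RMSET.

        Diverged repeats (non-finite loss) are dropped from the summary
        with a warning rather than aborting the whole selection.
        """
        if candidates is None:
            lo, hi = self.config.hidden_range
            candidates = list(range(lo, hi + 1))
        rows = []
        X, y = self.train.X, self.train.y
        for h in candidates:
            r2s, rmses = [], []
            for seed in self._repeat_seeds(h):
                try:
                    net = _train_network(X, y, h, self.config, seed)
                except TrainingDivergenceError as exc:
                    warnings.warn(f"h={h}: dropped diverged repeat ({exc})")
                    continue
                pred = net.predict(X)
                r2s.append(_r2_train(pred, y, form=self.config.r2_form))
                rmses.append(_rmse(pred, y))
            if not r2s:
                warnings.warn(f"h={h}: all repeats diverged; candidate skipped")
                continue
            rows.append({
                "h": h,
                "r2_min": min(r2s), "r2_max": max(r2s),
                "r2_mean": float(np.mean(r2s)),
                "rmse_min": min(rmses), "rmse_max": max(rmses),
                "rmse_mean": float(np.mean(rmses)),
                "n_repeats": len(r2s),
            })
        if not rows:
            raise TrainingDivergenceError("every candidate diverged")
        return pd.DataFrame(rows)

    def fit(self, h: int | None = None) -> CalibrationResult:
        """Select (or accept) the hidden size, train the final network."""
        table = None
        if h is None:
            table = self.selection_table()
            h = select_hidden_from_table(table)
        if h < 1:
            raise ParameterError("h must be >= 1")
        final_seed = int(np.random.SeedSequence(
            entropy=self.config.seed, spawn_key=(h, 0xF1A1)
        ).generate_state(1)[0] % (2**31))
        net = _train_network(self.train.X, self.train.y, h,
                             self.config, final_seed)
        return CalibrationResult(
            kind="bpnn",
            predict_fn=net.predict,
            n_features=self.train.n_features,
            hyperparams={"hidden_size": int(h)},
            selection=table,
            extra={"structure": f"{self.train.n_features}-{h}-1",
                   "activation": "tansig/purelin",
                   "seed": self.config.seed},
        )


def train_bpnn(train: Dataset, h: int, config: BPNNConfig | None = None,
               seed: int | None = None) -> CalibrationResult:
    """Train one network of hidden size ``h`` (no selection)."""
    config = config or BPNNConfig()
    if h < 1:
        raise ParameterError("h must be >= 1")
    if seed is None:
        seed = config.seed
    net = _train_network(train.X, train.y, h, config, seed)
    return CalibrationResult(
        kind="bpnn", predict_fn=net.predict, n_features=train.n_features,
        hyperparams={"hidden_size": int(h)},
        extra={"structure": f"{train.n_features}-{h}-1", "seed": seed},
    )


def select_hidden_size(train: Dataset, config: BPNNConfig | None = None):
    """Run the full selection protocol; return ``(h, selection table)``."""
    model = BPNNModel(train, config)
    table = model.selection_table()
    return select_hidden_from_table(table), table
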