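"""Kennard-Stone sample-set partitioning.

The Kennard-Stone algorithm picks a space-filling, representative
training subset from a feature matrix by greedy max-min selection under
Euclidean distance: seed with the two mutually farthest samples, then
repeatedly add the candidate whose minimum distance to the already
selected set is largest.  The selected samples form the training set;
the remainder form the validation set.  At the conventional 70/30 ratio
a 102-sample campaign splits 71/31.

Ties (equal distances) are broken toward the sample whose identifier
sorts first, making the partition deterministic and independent of the
input row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .exceptions import LengthError, ParameterError

__all__ = ["Partition", "train_count", "kennard_stone"]


@dataclass(frozen=True)
class Partition:
    """Ordered training / validation sample-id lists (disjoint, exhaustive)."""

    train_ids: tuple
    valid_ids: tuple

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.valid_ids)
        if overlap:
            raise ParameterError(f"ids in both sets: {sorted(overlap)}")

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.valid_ids)

    def to_dict(self) -> dict:
        return {"train": list(self.train_ids), "valid": list(self.valid_ids)}

    @classmethod
    def from_dict(cls, d: dict) -> "Partition":
        return cls(tuple(d["train"]), tuple(d["valid"]))


def train_count(n: int, ratio: float = 0.7) -> int:
    """Training-set size: floor(ratio * n), clamped to [2, n].

    floor matches the reference convention (0.7 * 102 = 71.4 -> 71).
    """
    if not 0 < ratio <= 1:
        raise ParameterError(f"ratio must be in (0, 1], got {ratio}")
    if n < 2:
        raise LengthError("need at least 2 samples")
    return int(min(n, max(2, math.floor(ratio * n + 1e-9))))


def kennard_stone(features, n_train: int, sample_ids=None) -> Partition:
    """Greedy max-min (Kennard-Stone) selection of a training subset.

    Parameters
    ----------
    features : array-like (n_samples, n_features) or DataFrame
        Feature matrix; for a DataFrame the index supplies sample ids.
    n_train : int
        Number of training samples to select, 2 <= n_train <= n.
    sample_ids : optional sequence of unique ids (default: DataFrame
        index, else 0..n-1).

    Returns
    -------
    Partition
        Training ids in selection order; validation ids in input order.
    """
    if isinstance(features, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    sample_ids = list(sample_ids)
    if len(sample_ids) != n:
        raise ParameterError("sample_ids length must match feature rows")
    if len(set(sample_ids)) != n:
        raise ParameterError("duplicate sample ids")
    if n < 2:
        raise LengthError("need at least 2 samples")
    if not 2 <= n_train <= n:
        raise LengthError(f"n_train must be in [2, {n}], got {n_train}")

    # rank of each row under sorted-id order: the deterministic tie-break
    order = {sid: rank for rank, sid in enumerate(sorted(sample_ids, key=str))}
    ordinal = np.array([order[sid] for sid in sample_ids])

    D = squareform(pdist(X, metric="euclidean"))

    # seed pair: maximum pairwise distance; ties -> smallest sorted-id pair
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((i, j), key=lambda k: ordinal[k])
            key = (-D[i, j], ordinal[a], ordinal[b])
            if best is None or key < best[0]:
                best = (key, a, b)
    _, i0, j0 = best

    selected = [i0, j0]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i0, j0]] = True
    min_dist = np.minimum(D[i0], D[j0])

    while len(selected) < n_train:
        cand = np.flatnonzero(~in_set)
        dists = min_dist[cand]
        best_d = dists.max()
        ties = cand[dists == best_d]
        pick = ties[np.argmin(ordinal[ties])]
        selected.append(int(pick))
        in_set[pick] = True
        min_dist = np.minimum(min_dist, D[pick])

    train_ids = tuple(sample_ids[i] for i in selected)
    valid_ids = tuple(sid for i, sid in enumerate(sample_ids) if not in_set[i])
    return Partition(train_ids=train_ids, valid_ids=valid_ids)
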