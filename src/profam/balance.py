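"""SMOTE minority oversampling.

Synthetic minority points are drawn on the segments between a minority row
and one of its k nearest minority neighbours (Euclidean on raw feature
values). ``percent`` follows the Weka filter convention the pipeline is
modelled on: percent=700 ADDS 7n synthetic rows to an n-row minority class,
for a total of 8n minority instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE parameters: percent added (multiples of 100 recommended), k, seed."""

    percent: int = 700
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.percent < 0:
            raise ValueError("percent must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def smote(minority_rows: np.ndarray, config: SmoteConfig) -> np.ndarray:
    """Generate ``floor(percent/100) * n`` synthetic rows from ``minority_rows``.

    Each synthetic row is x + u (z - x) with x a minority row, z one of its
    k nearest minority neighbours and u ~ Uniform(0, 1). When fewer than k
    neighbours exist (n - 1 < k) all n - 1 are used. Deterministic for a
    fixed seed.
    """
    X = np.asarray(minority_rows, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("minority_rows must be a 2-D n x d array")
    n = X.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    per_row = config.percent // 100
    if per_row == 0:
        return np.empty((0, X.shape[1]))

    k = min(config.k, n - 1)
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    # k nearest neighbours per row, nearest-first, index ties broken low-first
    order = np.argsort(d, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(config.seed)
    out = np.empty((per_row * n, X.shape[1]))
    pos = 0
    for _ in range(per_row):
        for i in range(n):
            z = X[order[i, rng.integers(k)]]
            u = rng.random()
            out[pos] = X[i] + u * (z - X[i])
            pos += 1
    return out


def rebalance_dataset(
    X: np.ndarray,
    y: np.ndarray,
    config: SmoteConfig,
    minority_label,
) -> tuple[np.ndarray, np.ndarray]:
    """Append SMOTE rows for ``minority_label``; original rows untouched.

    Returns (X', y') with the original rows first in their original order
    and the synthetic rows appended carrying the minority label.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask = y == minority_label
    if not mask.any():
        raise ValueError(f"minority label {minority_label!r} absent from y")
    if mask.all():
        raise ValueError("both classes must be present")
    if config.percent == 0:
        return X, y
    synth = smote(X[mask], config)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(len(synth), minority_label, dtype=y.dtype)])
    return X_out, y_out
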