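"""Feature preprocessing: Min-Max scaling and SMOTE rebalancing.

Both operations are fitted on / applied to training data only; test data is
transformed with training parameters and never resampled.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler


def minmax_fit(X_train: np.ndarray) -> MinMaxScaler:
    """Fit a [0, 1] Min-Max scaler on the training matrix.

    Constant training columns map to 0; at apply time, values outside the
    training range are clipped into [0, 1].
    """
    X_train = np.asarray(X_train, dtype=float)
    if not np.isfinite(X_train).all():
        raise ValueError("training matrix contains non-finite values")
    return MinMaxScaler(feature_range=(0.0, 1.0), clip=True).fit(X_train)


def minmax_apply(scaler: MinMaxScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(X, dtype=float))


class SmoteError(ValueError):
    pass


def smote_resample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling (SMOTE) to exactly balanced classes.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``,
    where ``x_nn`` is one of the ``k`` nearest minority-class neighbors
    (Euclidean) of a randomly chosen minority point ``x_i``; ``k`` is capped
    at minority size - 1.  Originals are retained and the output order is
    originals followed by synthetic rows.  Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise SmoteError(f"SMOTE needs exactly 2 classes, got {classes.size}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise SmoteError(
            "minority class has fewer than 2 samples; SMOTE cannot interpolate — "
            "drop this classification task"
        )
    k_eff = min(k, n_min - 1)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
    neigh = neigh[:, 1:]

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = X_min[base]
    partners = X_min[neigh[base, pick]]
    synthetic = anchors + u[:, np.newaxis] * (partners - anchors)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
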