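"""A compact numpy feed-forward binary classifier.

Supports the building blocks the classification stage needs: dense layers,
optional batch normalization, ReLU/tanh/sigmoid activations, inverted
dropout, skip connections that concatenate the raw input features onto a
hidden layer's output, Adam optimization of the binary cross-entropy, and
early stopping on a validation split with best-weight restoration.  Fully
deterministic for a fixed seed (single-threaded numpy, seeded init, shuffles
and dropout masks).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

_EPS = 1e-7
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class LayerSpec:
    """One hidden block: dense -> (batch norm) -> activation -> dropout,
    optionally followed by concatenating the network input (skip)."""

    units: int
    activation: str = "relu"
    dropout: float = 0.0
    batch_norm: bool = False
    skip_input: bool = False


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a held-out stratified subset (at least one per class)."""
    held = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_hold = max(1, int(round(fraction * idx.size))) if idx.size > 1 else 0
        held.append(idx[:n_hold])
    held_idx = np.sort(np.concatenate(held)) if held else np.array([], dtype=int)
    mask = np.ones(y.size, dtype=bool)
    mask[held_idx] = False
    return np.flatnonzero(mask), held_idx


class FeedForwardNet:
    """Binary classifier with the block structure given by ``layers``.

    Parameters mirror the training protocol of the classification stage:
    Adam with ``lr``, binary cross-entropy, mini-batches of ``batch_size``
    for up to ``epochs`` epochs, early stopping with ``patience`` epochs of
    no validation-loss improvement (best weights restored).  A stratified
    ``val_fraction`` split is carved from the training data unless an
    explicit validation set is passed to :meth:`fit`.
    """

    def __init__(
        self,
        n_features: int,
        layers: list[LayerSpec],
        lr: float = 1e-4,
        epochs: int = 100,
        batch_size: int = 8,
        patience: int = 10,
        val_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.layers = list(layers)
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._build()

    # ---- parameters ------------------------------------------------------
    def _build(self) -> None:
        self.params: list[dict[str, np.ndarray]] = []
        d = self.n_features
        for spec in self.layers:
            p: dict[str, np.ndarray] = {}
            if spec.activation == "relu":
                scale = np.sqrt(2.0 / d)  # He
            else:
                scale = np.sqrt(1.0 / d)  # Xavier-ish
            p["W"] = self._rng.normal(0.0, scale, size=(d, spec.units))
            p["b"] = np.zeros(spec.units)
            if spec.batch_norm:
                p["gamma"] = np.ones(spec.units)
                p["beta"] = np.zeros(spec.units)
                p["run_mean"] = np.zeros(spec.units)
                p["run_var"] = np.ones(spec.units)
            self.params.append(p)
            d = spec.units + (self.n_features if spec.skip_input else 0)
        self.out = {
            "W": self._rng.normal(0.0, np.sqrt(1.0 / d), size=(d, 1)),
            "b": np.zeros(1),
        }

    _TRAINABLE = ("W", "b", "gamma", "beta")

    def _trainable(self):
        for p in self.params + [self.out]:
            for k in self._TRAINABLE:
                if k in p:
                    yield p, k

    # ---- forward / backward ---------------------------------------------
    def _forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, list[dict]]:
        caches = []
        h = X
        for spec, p in zip(self.layers, self.params):
            cache: dict = {"in": h}
            z = h @ p["W"] + p["b"]
            if spec.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    p["run_mean"] = _BN_MOMENTUM * p["run_mean"] + (1 - _BN_MOMENTUM) * mu
                    p["run_var"] = _BN_MOMENTUM * p["run_var"] + (1 - _BN_MOMENTUM) * var
                else:
                    mu, var = p["run_mean"], p["run_var"]
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (z - mu) * inv_std
                z_bn = p["gamma"] * xhat + p["beta"]
                cache.update(z=z, xhat=xhat, inv_std=inv_std)
            else:
                z_bn = z
                cache["z"] = z
            a = _act(spec.activation, z_bn)
            cache["z_bn"] = z_bn
            cache["a"] = a
            if training and spec.dropout > 0:
                keep = 1.0 - spec.dropout
                mask = (self._rng.random(a.shape) < keep) / keep
                a = a * mask
                cache["mask"] = mask
            h = np.concatenate([a, X], axis=1) if spec.skip_input else a
            cache["out_width"] = a.shape[1]
            caches.append(cache)
        logits = h @ self.out["W"] + self.out["b"]
        caches.append({"in": h, "logits": logits})
        return logits, caches

    def _backward(
        self, X: np.ndarray, y: np.ndarray, caches: list[dict]
    ) -> list[dict[str, np.ndarray]]:
        n = X.shape[0]
        out_cache = caches[-1]
        p_hat = 1.0 / (1.0 + np.exp(-out_cache["logits"]))
        dlogits = (p_hat - y[:, np.newaxis]) / n  # BCE + sigmoid
        grads: list[dict[str, np.ndarray]] = [dict() for _ in self.params] + [dict()]
        grads[-1]["W"] = out_cache["in"].T @ dlogits
        grads[-1]["b"] = dlogits.sum(axis=0)
        dh = dlogits @ self.out["W"].T
        for i in range(len(self.layers) - 1, -1, -1):
            spec, p, cache = self.layers[i], self.params[i], caches[i]
            da = dh[:, : cache["out_width"]] if spec.skip_input else dh
            if "mask" in cache:
                da = da * cache["mask"]
            dz_bn = da * _act_grad(spec.activation, cache["z_bn"], cache["a"])
            if spec.batch_norm:
                xhat, inv_std = cache["xhat"], cache["inv_std"]
                m = dz_bn.shape[0]
                grads[i]["gamma"] = (dz_bn * xhat).sum(axis=0)
                grads[i]["beta"] = dz_bn.sum(axis=0)
                dxhat = dz_bn * p["gamma"]
                dz = (
                    inv_std
                    / m
                    * (
                        m * dxhat
                        - dxhat.sum(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0)
                    )
                )
            else:
                dz = dz_bn
            grads[i]["W"] = cache["in"].T @ dz
            grads[i]["b"] = dz.sum(axis=0)
            dh = dz @ p["W"].T
        return grads

    # ---- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "FeedForwardNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X_val is None:
            train_idx, val_idx = stratified_split(y, self.val_fraction, self._rng)
            if val_idx.size == 0:
                X_tr, y_tr, X_val, y_val = X, y, X, y
            else:
                X_tr, y_tr = X[train_idx], y[train_idx]
                X_val, y_val = X[val_idx], y[val_idx]
        else:
            X_tr, y_tr = X, y
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)

        # Adam state
        m_state = [{k: np.zeros_like(p[k]) for k in self._TRAINABLE if k in p}
                   for p in self.params + [self.out]]
        v_state = copy.deepcopy(m_state)
        t = 0
        best_loss = np.inf
        best_params: tuple | None = None
        stall = 0
        n = X_tr.shape[0]
        for _epoch in range(self.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                if batch.size < 2 and n >= 2:
                    continue  # batch norm needs >= 2 rows; remainder folded away
                _, caches = self._forward(X_tr[batch], training=True)
                grads = self._backward(X_tr[batch], y_tr[batch], caches)
                t += 1
                b1c = 1.0 - 0.9**t
                b2c = 1.0 - 0.999**t
                all_params = self.params + [self.out]
                for slot, p in enumerate(all_params):
                    for k in self._TRAINABLE:
                        if k not in p:
                            continue
                        g = grads[slot][k]
                        m_state[slot][k] = 0.9 * m_state[slot][k] + 0.1 * g
                        v_state[slot][k] = 0.999 * v_state[slot][k] + 0.001 * g * g
                        mhat = m_state[slot][k] / b1c
                        vhat = v_state[slot][k] / b2c
                        p[k] -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)
            val_loss = binary_cross_entropy(y_val, self.predict_score(X_val))
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_params = (copy.deepcopy(self.params), copy.deepcopy(self.out))
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_params is not None:
            self.params, self.out = best_params
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X) >= threshold).astype(int)
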