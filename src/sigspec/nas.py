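"""Neural architecture search over a small feed-forward design space.

The search space Omega is the Cartesian product of per-option sets: number
of hidden layers (1-3), neurons per layer (8-64), a shared activation
(relu/tanh/sigmoid), a shared dropout rate (0-0.5), batch normalization
on/off, and optional skip connections feeding the raw input into layers 2
and 3.  The search maximizes validation F1,

    alpha* = argmax_{alpha in Omega} f(alpha),

with a Bayesian strategy: an initial random phase, then a Gaussian-process
surrogate (Matern + white noise) over encoded architectures proposing the
expected-improvement maximizer among a pool of random candidates.  The whole
procedure is deterministic under the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.metrics import f1_score

from .nn import FeedForwardNet, LayerSpec, stratified_split

_ACTIVATIONS = ("relu", "tanh", "sigmoid")
MIN_BUDGET = 5
_N_INIT = 5
_CANDIDATE_POOL = 128


@dataclass(frozen=True)
class Architecture:
    n_layers: int
    units: tuple[int, ...]
    activation: str
    dropout: float
    batch_norm: bool
    skips: tuple[bool, ...]  # for layers 2..n_layers

    def layer_specs(self) -> list[LayerSpec]:
        specs = []
        for i in range(self.n_layers):
            skip = self.skips[i - 1] if i >= 1 and i - 1 < len(self.skips) else False
            specs.append(
                LayerSpec(
                    units=self.units[i],
                    activation=self.activation,
                    dropout=self.dropout,
                    batch_norm=self.batch_norm,
                    skip_input=skip,
                )
            )
        return specs


@dataclass
class SearchSpace:
    """Option sets whose Cartesian product is the search space."""

    n_layers_options: tuple[int, ...] = (1, 2, 3)
    units_range: tuple[int, int] = (8, 64)
    activations: tuple[str, ...] = _ACTIVATIONS
    dropout_range: tuple[float, float] = (0.0, 0.5)
    batch_norm_options: tuple[bool, ...] = (False, True)
    skip_options: tuple[bool, ...] = (False, True)

    def __post_init__(self) -> None:
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        lo, hi = self.units_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid units range")

    def sample(self, rng: np.random.Generator) -> Architecture:
        n_layers = int(rng.choice(self.n_layers_options))
        lo, hi = self.units_range
        units = tuple(int(rng.integers(lo, hi + 1)) for _ in range(n_layers))
        activation = str(rng.choice(self.activations))
        d_lo, d_hi = self.dropout_range
        dropout = float(rng.uniform(d_lo, d_hi)) if d_hi > d_lo else float(d_lo)
        batch_norm = bool(rng.choice(self.batch_norm_options))
        skips = tuple(bool(rng.choice(self.skip_options)) for _ in range(n_layers - 1))
        return Architecture(n_layers, units, activation, dropout, batch_norm, skips)

    def encode(self, arch: Architecture) -> np.ndarray:
        """Fixed-length numeric encoding, roughly unit-scaled, for the surrogate."""
        lo, hi = self.units_range
        span = max(hi - lo, 1)
        units = list(arch.units) + [0] * (3 - arch.n_layers)
        skips = list(arch.skips) + [False] * (2 - len(arch.skips))
        return np.array(
            [
                arch.n_layers / 3.0,
                *[(u - lo) / span if u else 0.0 for u in units],
                _ACTIVATIONS.index(arch.activation) / 2.0,
                arch.dropout,
                float(arch.batch_norm),
                float(skips[0]),
                float(skips[1]),
            ]
        )


@dataclass
class NASResult:
    model: "TrainedModel"
    architecture: Architecture
    best_score: float
    trials: list[tuple[Architecture, float]] = field(default_factory=list)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def nas_search(
    space: SearchSpace,
    ft,
    budget: int = 25,
    seed: int = 0,
    epochs: int = 60,
    lr: float = 1e-3,
    batch_size: int = 16,
    patience: int = 10,
) -> NASResult:
    """Search ``budget`` architectures for the best validation F1.

    A 20% stratified validation split is carved once from *ft*; every
    candidate is trained on the remainder (with early stopping against the
    same split) and scored by validation F1 at the 0.5 threshold.  Returns
    the best trial's trained network, its architecture, and the full trial
    log.
    """
    from .ml import TrainedModel  # deferred: ml imports nas lazily too

    if budget < MIN_BUDGET:
        raise ValueError(f"NAS budget must be >= {MIN_BUDGET}, got {budget}")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = stratified_split(ft.y, 0.2, rng)
    if val_idx.size == 0:
        raise ValueError("training set too small to carve a validation split")
    X_tr, y_tr = ft.X[train_idx], ft.y[train_idx]
    X_val, y_val = ft.X[val_idx], ft.y[val_idx]

    trials: list[tuple[Architecture, float]] = []
    encodings: list[np.ndarray] = []
    scores: list[float] = []
    nets: list[FeedForwardNet] = []

    def run_trial(arch: Architecture) -> None:
        net = FeedForwardNet(
            n_features=ft.X.shape[1],
            layers=arch.layer_specs(),
            lr=lr,
            epochs=epochs,
            batch_size=batch_size,
            patience=patience,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).fit(X_tr, y_tr, X_val, y_val)
        score = float(f1_score(y_val, net.predict_label(X_val), zero_division=0))
        trials.append((arch, score))
        encodings.append(space.encode(arch))
        scores.append(score)
        nets.append(net)

    n_init = min(_N_INIT, budget)
    for _ in range(n_init):
        run_trial(space.sample(rng))

    kernel = Matern(nu=2.5, length_scale=1.0) + WhiteKernel(noise_level=1e-3)
    for _ in range(budget - n_init):
        candidates = [space.sample(rng) for _ in range(_CANDIDATE_POOL)]
        enc = np.array([space.encode(c) for c in candidates])
        X_obs = np.array(encodings)
        y_obs = np.array(scores)
        if np.ptp(y_obs) < 1e-12 or np.allclose(np.ptp(X_obs, axis=0), 0):
            # flat observations or degenerate space: nothing for a surrogate
            chosen = candidates[0]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp = GaussianProcessRegressor(
                    kernel=kernel, normalize_y=True, random_state=0
                ).fit(X_obs, y_obs)
                mu, sigma = gp.predict(enc, return_std=True)
            ei = _expected_improvement(mu, sigma, max(scores))
            chosen = candidates[int(np.argmax(ei))]
        run_trial(chosen)

    best = int(np.argmax(scores))
    model = TrainedModel("NAS", nets[best], ft.feature_ids)
    return NASResult(model, trials[best][0], scores[best], trials)
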