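"""One-vs-rest cancer-type classification from signature exposure profiles.

Five methods, each a binary classifier scoring "is this sample the target
cancer type" from the K signature features:

* ``RF``  — random forest, 100 trees, sqrt feature subsampling, Gini.
* ``XGB`` — gradient boosted trees (XGBoost), 100 rounds, depth 6, eta 0.3,
            logistic loss.
* ``MLP`` — scikit-learn multilayer perceptron, hidden layers (32, 16),
            L-BFGS solver, alpha 1e-4.
* ``DNN`` — numpy feed-forward net: 32-ReLU + dropout 0.2 + input skip,
            8-ReLU + dropout 0.2 + input skip, sigmoid output; Adam lr 1e-4,
            binary cross-entropy, 100 epochs, batch 8, early stopping
            (patience 10) on a 20% stratified validation split.
* ``NAS`` — architecture found by Bayesian-optimization search over a small
            feed-forward design space (see :mod:`sigspec.nas`).

Labels use a 0.5 threshold on the predicted score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score as _sk_f1
from sklearn.neural_network import MLPClassifier

from .nn import FeedForwardNet, LayerSpec

METHODS = ("RF", "XGB", "MLP", "DNN", "NAS")
_METHOD_ALIASES = {"GBT": "XGB", "XGBOOST": "XGB"}


@dataclass
class FeatureTable:
    """Samples x signature-features design matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    def relabel(self, y: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X, y, self.sample_ids, self.feature_ids)


@dataclass
class ModelSpec:
    method: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.method = _METHOD_ALIASES.get(self.method.upper(), self.method.upper())
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


class TrainedModel:
    """Uniform prediction surface over the five methods."""

    def __init__(self, method: str, inner, feature_ids: list[str], extra: dict | None = None):
        self.method = method
        self.inner = inner
        self.feature_ids = list(feature_ids)
        self.extra = extra or {}

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if isinstance(self.inner, FeedForwardNet):
            return self.inner.predict_score(X)
        return self.inner.predict_proba(X)[:, 1]

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X) >= threshold).astype(int)


def _dnn_layers() -> list[LayerSpec]:
    return [
        LayerSpec(units=32, activation="relu", dropout=0.2, skip_input=True),
        LayerSpec(units=8, activation="relu", dropout=0.2, skip_input=True),
    ]


def train_model(spec: ModelSpec, ft: FeatureTable) -> TrainedModel:
    """Train one binary classifier; deterministic under ``spec.seed``."""
    if np.unique(ft.y).size < 2:
        raise ValueError("training labels contain a single class")
    hp = dict(spec.hyperparameters)
    if spec.method == "RF":
        inner = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_features="sqrt",
            criterion="gini",
            random_state=spec.seed,
            n_jobs=1,
        ).fit(ft.X, ft.y)
    elif spec.method == "XGB":
        from xgboost import XGBClassifier

        inner = XGBClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_depth=hp.pop("max_depth", 6),
            learning_rate=hp.pop("learning_rate", 0.3),
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        ).fit(ft.X, ft.y)
    elif spec.method == "MLP":
        inner = MLPClassifier(
            hidden_layer_sizes=(32, 16),
            solver="lbfgs",
            alpha=1e-4,
            max_iter=hp.pop("max_iter", 500),
            random_state=spec.seed,
        ).fit(ft.X, ft.y)
    elif spec.method == "DNN":
        inner = FeedForwardNet(
            n_features=ft.X.shape[1],
            layers=_dnn_layers(),
            lr=hp.pop("lr", 1e-4),
            epochs=hp.pop("epochs", 100),
            batch_size=hp.pop("batch_size", 8),
            patience=hp.pop("patience", 10),
            val_fraction=0.2,
            seed=spec.seed,
        ).fit(ft.X, ft.y)
    elif spec.method == "NAS":
        from .nas import SearchSpace, nas_search

        result = nas_search(
            hp.pop("space", SearchSpace()),
            ft,
            budget=hp.pop("budget", 25),
            seed=spec.seed,
            **hp,
        )
        model = result.model
        model.extra["architecture"] = result.architecture
        model.extra["trials"] = result.trials
        return model
    else:  # pragma: no cover
        raise AssertionError(spec.method)
    return TrainedModel(spec.method, inner, ft.feature_ids)


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float
    n_positive: int


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties share ranks)."""
    from scipy.stats import rankdata

    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model: TrainedModel, ft_test: FeatureTable, threshold: float = 0.5) -> EvalMetrics:
    """Precision/recall/F1/accuracy on 0.5-threshold labels, rank AUC on scores."""
    y = ft_test.y
    n_positive = int(y.sum())
    if n_positive == 0:
        raise ValueError("no positive test samples; one-vs-rest evaluation undefined")
    scores = model.predict_score(ft_test.X)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = f1_from_precision_recall(precision, recall)
    accuracy = float((pred == y).mean())
    auc = _rank_auc(scores, y)
    return EvalMetrics(precision, recall, f1, accuracy, auc, n_positive)


def feature_importance(
    model: TrainedModel,
    ft: FeatureTable,
    seed: int = 0,
    n_repeats: int = 10,
) -> list[tuple[str, float]]:
    """Ranked feature importances.

    Tree models report normalized impurity importances (sum 1); the neural
    models report permutation importance, the mean F1 drop over ``n_repeats``
    per-feature shuffles of *ft*.  Descending by importance, ties broken by
    feature id.
    """
    if model.method in ("RF", "XGB"):
        imp = np.asarray(model.inner.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        else:
            warnings.warn("all impurity importances are zero", stacklevel=2)
    else:
        rng = np.random.default_rng(seed)
        base = _sk_f1(ft.y, model.predict_label(ft.X), zero_division=0)
        imp = np.zeros(len(ft.feature_ids))
        for j in range(len(ft.feature_ids)):
            drops = []
            for _ in range(n_repeats):
                Xp = ft.X.copy()
                Xp[:, j] = Xp[rng.permutation(Xp.shape[0]), j]
                drops.append(base - _sk_f1(ft.y, model.predict_label(Xp), zero_division=0))
            imp[j] = np.mean(drops)
    order = sorted(
        range(len(ft.feature_ids)), key=lambda j: (-imp[j], ft.feature_ids[j])
    )
    return [(ft.feature_ids[j], float(imp[j])) for j in order]
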