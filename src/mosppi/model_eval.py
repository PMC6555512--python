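"""Classifier training and evaluation for pair-feature tables.

The reference classifier is a fully connected feed-forward network:
``depth`` hidden layers of ``width`` ReLU units, a logistic output, and
mean binary cross-entropy minimized with Adam in minibatches.  The
selected configuration is learning rate 0.01, width 512, depth 3, batch
size 128 and no dropout; a preset with (lr 0.001, width 256, depth 3) is
provided for the comparison encoders.  Training length is expressed in
minibatch *steps* and converted internally to whole passes over the data.

Metrics: accuracy (TP+TN)/(TP+TN+FP+FN) and recall TP/(TP+FN) at a 0.5
decision threshold, trapezoidal ROC AUC (ties counted 1/2), and the
clipped mean binary cross-entropy

    loss = -(1/n) * sum_i [ y*_i ln y_i + (1 - y*_i) ln(1 - y_i) ]

with probabilities clipped to [1e-12, 1 - 1e-12].

Repeated hold-out validation re-splits, re-trains and re-evaluates with
derived seeds, reporting each metric as mean ± sample standard deviation.
Off-the-shelf decision-tree, k-neighbors and random-forest classifiers are
exposed through the same fit/predict surface for encoder/classifier
comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .dataset_io import PairFeatureTable, split_train_holdout

__all__ = [
    "ModelConfig",
    "BASELINE_ENCODER_PRESET",
    "EvalMetrics",
    "MLPPairClassifier",
    "train_mlp",
    "predict",
    "evaluate",
    "holdout_repeat",
    "classic_classifier",
    "format_mean_std",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the feed-forward classifier.

    Defaults are the selected configuration (lr 0.01, 512x512x512, batch
    128, dropout 0); ``n_steps`` counts minibatch updates.
    """

    learning_rate: float = 0.01
    width: int = 512
    depth: int = 3
    activation: str = "relu"
    optimizer: str = "adam"
    batch_size: int = 128
    dropout: float = 0.0
    n_steps: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.depth < 1:
            raise ValueError("width and depth must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.n_steps < 1:
            raise ValueError("batch_size and n_steps must be >= 1")


#: Configuration used for the CT/AC/LD comparison models.
BASELINE_ENCODER_PRESET = ModelConfig(learning_rate=0.001, width=256, depth=3)


class MLPPairClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward pair classifier (dense ReLU layers + logistic output).

    scikit-learn estimator over an (n_pairs, per_pair_dim) feature matrix
    and 0/1 labels.  ``n_steps`` minibatch updates are converted to
    ``ceil(n_steps / steps_per_epoch)`` full passes.  Only ``dropout=0``
    is supported by the dense backend; any other value raises at fit time.
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        width: int = 512,
        depth: int = 3,
        batch_size: int = 128,
        n_steps: int = 2000,
        dropout: float = 0.0,
        activation: str = "relu",
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.width = width
        self.depth = depth
        self.batch_size = batch_size
        self.n_steps = n_steps
        self.dropout = dropout
        self.activation = activation
        self.seed = seed

    @classmethod
    def from_config(cls, config: ModelConfig) -> "MLPPairClassifier":
        if config.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {config.optimizer!r}")
        return cls(
            learning_rate=config.learning_rate,
            width=config.width,
            depth=config.depth,
            batch_size=config.batch_size,
            n_steps=config.n_steps,
            dropout=config.dropout,
            activation=config.activation,
            seed=config.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty table")
        if self.dropout != 0.0:
            raise ValueError(
                "only dropout=0 is supported by the dense network backend"
            )
        n = X.shape[0]
        batch = min(self.batch_size, n)
        steps_per_epoch = math.ceil(n / batch)
        epochs = max(1, math.ceil(self.n_steps / steps_per_epoch))
        self.n_epochs_ = epochs
        self._mlp = MLPClassifier(
            hidden_layer_sizes=(self.width,) * self.depth,
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=batch,
            max_iter=epochs,
            shuffle=True,
            random_state=self.seed,
            tol=0.0,              # run the full step budget
            n_iter_no_change=epochs + 1,
            alpha=0.0,
        )
        with warnings.catch_warnings():
            # hitting the configured step budget is intended, not a failure
            warnings.filterwarnings(
                "ignore", message=".*Maximum iterations.*", category=Warning
            )
            self._mlp.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = self._mlp.classes_
        self.loss_curve_ = list(self._mlp.loss_curve_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._mlp.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        if proba.shape[0] == 0:
            return np.empty((0,), dtype=np.int64)
        return (proba[:, 1] >= 0.5).astype(np.int64)


def train_mlp(train: PairFeatureTable, config: ModelConfig) -> MLPPairClassifier:
    """Fit the feed-forward classifier on a training pair table."""
    clf = MLPPairClassifier.from_config(config)
    return clf.fit(train.X, train.y)


def predict(model, table: PairFeatureTable) -> np.ndarray:
    """Per-row probability of interaction (class 1)."""
    proba = model.predict_proba(table.X)
    if proba.shape[0] == 0:
        return np.empty((0,))
    return proba[:, 1]


@dataclass(frozen=True)
class EvalMetrics:
    """Metrics of one evaluation run, with the underlying confusion counts."""

    accuracy: float
    recall: float
    auc: float
    loss: float
    tp: int
    tn: int
    fp: int
    fn: int
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(labels, probs, threshold: float = 0.5) -> EvalMetrics:
    """Compute accuracy, recall, trapezoidal ROC AUC and cross-entropy loss.

    ``labels`` are 0/1; ``probs`` are interaction probabilities.  AUC is
    reported as NaN (with a warning) when only one class is present; an
    empty input raises.
    """
    y = np.asarray(labels)
    p = np.asarray(probs, dtype=np.float64)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and probs must be equal-length 1-D arrays")
    if y.size == 0:
        raise ValueError("cannot evaluate on empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")

    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    accuracy = (tp + tn) / y.size
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    if len(np.unique(y)) < 2:
        warnings.warn("AUC undefined for single-class labels", stacklevel=2)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, p))

    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    return EvalMetrics(accuracy, recall, auc, loss, tp, tn, fp, fn, int(y.size))


def format_mean_std(mean: float, std: float, digits: int = 4) -> str:
    """Render a metric as in benchmark tables, e.g. ``0.9434±0.0078``."""
    return f"{round(mean, digits)}±{round(std, digits)}"


def holdout_repeat(
    table: PairFeatureTable,
    config: ModelConfig,
    n_repeats: int,
    base_seed: int,
    train_fraction: float = 0.75,
    n_train_pos: int | None = None,
    n_train_neg: int | None = None,
    model_factory=None,
):
    """Repeated hold-out validation.

    Each repeat draws a fresh stratified split with a seed derived from
    ``base_seed``, trains a fresh model, and evaluates on the held-out
    remainder.  Per-class training counts default to ``train_fraction`` of
    each class.  Returns ``(summary, runs)`` where ``summary`` maps each
    metric name to ``(mean, sample std)`` (std 0 for a single repeat, by
    convention) and ``runs`` is the list of per-repeat
    :class:`EvalMetrics`.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if n_train_pos is None:
        n_train_pos = int(train_fraction * table.n_pos)
    if n_train_neg is None:
        n_train_neg = int(train_fraction * table.n_neg)

    seeds = np.random.SeedSequence(base_seed).generate_state(n_repeats) % (2**31)
    runs: list[EvalMetrics] = []
    for r in range(n_repeats):
        run_seed = int(seeds[r])
        train, holdout = split_train_holdout(
            table, n_train_pos, n_train_neg, seed=run_seed
        )
        if model_factory is None:
            model = train_mlp(train, replace(config, seed=run_seed))
        else:
            model = model_factory(run_seed).fit(train.X, train.y)
        runs.append(evaluate(holdout.y, predict(model, holdout)))

    summary = {}
    for name in ("accuracy", "recall", "auc", "loss"):
        vals = np.array([getattr(m, name) for m in runs], dtype=np.float64)
        std = float(vals.std(ddof=1)) if n_repeats > 1 else 0.0
        summary[name] = (float(vals.mean()), std)
    return summary, runs


_CLASSIC = {
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "k_neighbors": lambda seed: KNeighborsClassifier(),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=200, random_state=seed, n_jobs=1
    ),
}


def classic_classifier(train: PairFeatureTable, algorithm: str, seed: int = 0):
    """Fit an off-the-shelf classifier (decision_tree | k_neighbors | random_forest)."""
    if algorithm not in _CLASSIC:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(_CLASSIC)}"
        )
    if train.n_rows == 0:
        raise ValueError("cannot fit on an empty table")
    model = _CLASSIC[algorithm](seed)
    return model.fit(train.X, train.y)
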