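"""The three supervised segment classifiers with a uniform fit/predict contract.

* :class:`SVMSegmentClassifier` — RBF support vector machine on standardized
  entropy features.
* :class:`FCNNClassifier` — fully connected net, two hidden layers of 32,
  2-logit softmax output, cross-entropy, Adam, batch 64.
* :class:`CNNClassifier` — 3x3 convolution with 32 filters, 2x2 max pooling,
  128-unit hidden layer, 2-logit softmax output, Adam, batch 64; operates on
  small images (the 8x6/8x7 entropy matrix or a resized spectrogram).

All estimators are scikit-learn compatible (``get_params``/``set_params``,
fitted attributes with trailing underscores) and deterministic given their
seed. Networks trained with an ``eval_set`` record the per-epoch test
accuracy in ``epoch_trace_`` (percent), mirroring how accuracies are
summarized over the last training epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _nn
from .core_io import ConfigError, SOZ


@dataclass
class ModelSpec:
    """Declarative model description used by :func:`build_model`."""

    kind: str  # {"svm", "fcnn", "cnn"}
    input_dim: int | None = None
    input_hw: tuple[int, int] | None = None
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class TrainResult:
    """A trained predictor plus its per-epoch test-accuracy trace."""

    model: object
    epoch_trace: np.ndarray
    standardizer: StandardScaler | None = None


def _validate_binary(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary binary labels to integer codes with SOZ as class 1."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise ConfigError(f"need exactly 2 classes in training labels, got {list(classes)}")
    # put the positive (SOZ) class last so index 1 is "SOZ-like"
    if SOZ in classes:
        classes = np.array([c for c in classes if c != SOZ] + [SOZ], dtype=classes.dtype)
    codes = np.array([np.where(classes == v)[0][0] for v in y], dtype=int)
    return classes, codes


class _EpochTrainerMixin:
    """Shared minibatch Adam loop with per-epoch evaluation."""

    def _train_loop(self, net, X, y_codes, eval_set, classes):
        rng = np.random.default_rng(self.seed + 1)
        opt = _nn.Adam(net.params, lr=self.lr)
        n = len(X)
        trace = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net.forward(X[idx])
                _, grad = _nn.cross_entropy_grad(logits, y_codes[idx])
                net.backward(grad)
                opt.step()
            if eval_set is not None:
                Xe, ye = eval_set
                acc = 100.0 * float(np.mean(self._predict_from(net, Xe, classes) == ye))
            else:
                acc = 100.0 * float(
                    np.mean(self._predict_from(net, X, classes) == classes[y_codes])
                )
            trace.append(acc)
        return np.asarray(trace)


class FCNNClassifier(_EpochTrainerMixin, BaseEstimator, ClassifierMixin):
    """Two-hidden-layer (32, 32) fully connected classifier.

    Features are z-scored with statistics fit on the training rows only.
    """

    def __init__(self, hidden=(32, 32), epochs: int = 100, batch_size: int = 64,
                 lr: float = 1e-3, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, X, y, eval_set=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = _validate_binary(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        rng = np.random.default_rng(self.seed)
        self.net_ = _nn.make_mlp(X.shape[1], tuple(self.hidden), 2, rng)
        if eval_set is not None:
            eval_set = (self.scaler_.transform(np.asarray(eval_set[0], dtype=float)),
                        np.asarray(eval_set[1]))
        self.epoch_trace_ = self._train_loop(self.net_, Xs, codes, eval_set, self.classes_)
        return self

    @staticmethod
    def _predict_from(net, Xs, classes):
        return classes[np.argmax(net.forward(Xs), axis=1)]

    def predict(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        if len(Xs) == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self._predict_from(self.net_, Xs, self.classes_)

    def predict_proba(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return _nn.softmax(self.net_.forward(Xs))

    def decision_function(self, X):
        """Logit margin for the positive (SOZ-like) class."""
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        logits = self.net_.forward(Xs)
        return logits[:, 1] - logits[:, 0]

    def n_parameters(self) -> int:
        return self.net_.n_parameters()


class CNNClassifier(_EpochTrainerMixin, BaseEstimator, ClassifierMixin):
    """Small convolutional classifier on (n, H, W) images in [0, 1]."""

    def __init__(self, n_filters: int = 32, kernel: int = 3, hidden: int = 128,
                 epochs: int = 100, batch_size: int = 64, lr: float = 1e-3,
                 seed: int = 0):
        self.n_filters = n_filters
        self.kernel = kernel
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, X, y, eval_set=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ConfigError("CNN input must be (n, H, W) images")
        y = np.asarray(y)
        self.classes_, codes = _validate_binary(y)
        self.input_hw_ = X.shape[1:]
        rng = np.random.default_rng(self.seed)
        self.net_ = _nn.make_cnn(self.input_hw_, self.n_filters, self.kernel,
                                 self.hidden, 2, rng)
        if eval_set is not None:
            eval_set = (np.asarray(eval_set[0], dtype=float), np.asarray(eval_set[1]))
        self.epoch_trace_ = self._train_loop(self.net_, X, codes, eval_set, self.classes_)
        return self

    @staticmethod
    def _predict_from(net, X, classes):
        return classes[np.argmax(net.forward(X), axis=1)]

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        if X.shape[1:] != self.input_hw_:
            raise ConfigError(
                f"image shape {X.shape[1:]} does not match fitted {self.input_hw_}"
            )
        return self._predict_from(self.net_, X, self.classes_)

    def predict_proba(self, X):
        return _nn.softmax(self.net_.forward(np.asarray(X, dtype=float)))

    def n_parameters(self) -> int:
        return self.net_.n_parameters()


class SVMSegmentClassifier(BaseEstimator, ClassifierMixin):
    """RBF support vector machine on standardized features.

    ``epochs`` is accepted for interface uniformity; fitting is a single
    solve and the epoch trace is a constant vector.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 kernel: str = "rbf", epochs: int = 100, seed: int = 0):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y, eval_set=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, _ = _validate_binary(y)
        self.scaler_ = StandardScaler().fit(X)
        self.svc_ = SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                        random_state=self.seed)
        self.svc_.fit(self.scaler_.transform(X), y)
        if eval_set is not None:
            acc = 100.0 * float(np.mean(self.predict(eval_set[0]) == eval_set[1]))
        else:
            acc = 100.0 * float(np.mean(self.predict(X) == y))
        self.epoch_trace_ = np.full(self.epochs, acc)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.svc_.predict(self.scaler_.transform(X))

    def decision_function(self, X):
        return self.svc_.decision_function(self.scaler_.transform(np.asarray(X, float)))


def build_model(spec: ModelSpec):
    """Instantiate an untrained classifier from a :class:`ModelSpec`."""
    hp = dict(spec.hyperparams)
    if spec.kind == "svm":
        return SVMSegmentClassifier(seed=spec.seed, **hp)
    if spec.kind == "fcnn":
        return FCNNClassifier(seed=spec.seed, **hp)
    if spec.kind == "cnn":
        return CNNClassifier(seed=spec.seed, **hp)
    raise ConfigError(f"unknown model kind {spec.kind!r}")


def train_supervised(model, X_train, y_train, X_test=None, y_test=None,
                     epochs: int | None = None) -> TrainResult:
    """Fit any of the three classifiers and package the epoch trace."""
    if epochs is not None:
        model.set_params(epochs=epochs)
    eval_set = (X_test, y_test) if X_test is not None else None
    model.fit(X_train, y_train, eval_set=eval_set)
    return TrainResult(
        model=model,
        epoch_trace=model.epoch_trace_,
        standardizer=getattr(model, "scaler_", None),
    )


def predict(model_or_result, X):
    """Labels and SOZ-class scores from a trained model or TrainResult."""
    model = model_or_result.model if isinstance(model_or_result, TrainResult) else model_or_result
    labels = model.predict(X)
    if len(np.asarray(X)) == 0:
        return labels, np.empty(0)
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)[:, list(model.classes_).index(SOZ)
                                        if SOZ in model.classes_ else 1]
    else:
        scores = model.decision_function(X)
        if SOZ in model.classes_ and list(model.classes_)[-1] != SOZ:
            scores = -scores
    return labels, scores
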