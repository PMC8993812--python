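"""Frame-level severity classifiers.

Every model maps one input unit — a 96x64 log-mel voice window, a 19x129
linear accelerometer spectrogram, or a 1 Hz feature vector — to per-function
5-class sigmoid activations, one activation per (function, score) label.
Training minimizes a per-label logistic loss in which each frame is weighted
inversely to the frame-level frequency of its class label, so participants
with many recordings do not dominate.  A linear-regression variant trained
with squared error on the integer score is included for comparison; its
continuous prediction is mapped to a pseudo-distribution over classes via a
distance softmax so it can enter the same AUC comparisons.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``), store fitted state in trailing-underscore attributes, and
are deterministic given ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _nn
from .alsfrs import N_CLASSES

__all__ = [
    "ModelConfig",
    "FramePrediction",
    "class_weights",
    "SpectrogramCNNClassifier",
    "FeatureMLPClassifier",
    "FeatureLogisticClassifier",
    "FeatureLinearRegressor",
    "build_model",
    "train",
    "predict_frames",
]


def class_weights(frame_labels) -> dict[int, float]:
    """Inverse-class-frequency frame weights, normalized to unit mean.

    ``w_k`` is proportional to ``1 / count_k`` for the classes present, and
    rescaled so the weighted mean over frames equals 1 (``sum_k w_k count_k
    = n``).  Equal class counts give all weights 1; a single present class
    gets weight 1.  Absent classes carry no entry.
    """
    labels = np.asarray(frame_labels)
    if labels.size == 0:
        raise ValueError("frame_labels must be nonempty")
    classes, counts = np.unique(labels, return_counts=True)
    k = len(classes)
    n = labels.size
    return {int(c): float(n / (k * cnt)) for c, cnt in zip(classes, counts)}


@dataclass(frozen=True)
class FramePrediction:
    """Per-function class activations and normalized probabilities for one window."""

    functions: tuple[str, ...]
    activations: np.ndarray    # (n_functions, 5) raw sigmoid outputs in [0, 1]
    probabilities: np.ndarray  # (n_functions, 5) normalized to sum to 1

    def distribution(self, function: str) -> np.ndarray:
        return self.probabilities[self.functions.index(function)]


def _normalize_activations(act: np.ndarray) -> np.ndarray:
    """Rescale per-class sigmoid activations into proper distributions."""
    total = act.sum(axis=-1, keepdims=True)
    n = act.shape[-1]
    # all-zero activations normalize to the uniform distribution
    return np.where(total > 0, act / np.where(total > 0, total, 1.0), 1.0 / n)


class _FrameNetBase(BaseEstimator):
    """Shared fit/predict machinery for the sigmoid-per-label classifiers."""

    def __init__(
        self,
        target_functions=None,
        learning_rate: float = 1e-3,
        batch_size: int = 100,
        epochs: int = 60,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        self.target_functions = target_functions
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.random_state = random_state

    # subclasses build the network --------------------------------------
    def _build_net(self, input_shape, n_outputs, rng) -> _nn.Sequential:
        raise NotImplementedError

    def _prepare_X(self, X) -> np.ndarray:
        return np.asarray(X, dtype=np.float64)

    # ---------------------------------------------------------------
    def _resolve_functions(self, y) -> tuple[str, ...]:
        if self.target_functions is not None:
            if isinstance(self.target_functions, str):
                return (self.target_functions,)
            return tuple(self.target_functions)
        n_funcs = 1 if y.ndim == 1 else y.shape[1]
        return tuple(f"function_{i}" for i in range(n_funcs))

    def fit(self, X, y, validation_data=None):
        """Fit on windows X and integer score labels y (0-4).

        ``y`` has shape (n,) for a single-function head or (n, n_functions)
        for the multi-label head.  If ``validation_data=(X_val, y_val)`` is
        given, the parameters achieving the best validation macro multiclass
        AUC are restored after the final epoch.
        """
        from .evaluation import multiclass_auc  # local import, no cycle

        X = self._prepare_X(X)
        y = np.asarray(y)
        if y.ndim == 1:
            y2 = y[:, None]
        else:
            y2 = y
        if X.shape[0] != y2.shape[0]:
            raise ValueError("X and y have different numbers of frames")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on zero frames")
        if not np.isin(y2, np.arange(N_CLASSES)).all():
            raise ValueError("labels must be integers in 0..4")

        self.functions_ = self._resolve_functions(y)
        n_funcs = len(self.functions_)
        if y2.shape[1] != n_funcs:
            raise ValueError(
                f"y has {y2.shape[1]} label columns but {n_funcs} target functions"
            )
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X.shape[1:], n_funcs * N_CLASSES, rng)
        self.class_weights_ = [class_weights(y2[:, f]) for f in range(n_funcs)]
        self.classes_ = np.arange(N_CLASSES)

        # per-frame weight tensor, broadcast over a function's 5 labels
        w = np.empty((X.shape[0], n_funcs, N_CLASSES))
        for f in range(n_funcs):
            lut = np.ones(N_CLASSES)
            for c, wc in self.class_weights_[f].items():
                lut[c] = wc
            w[:, f, :] = lut[y2[:, f]][:, None]
        w = w.reshape(X.shape[0], -1)
        targets = np.zeros((X.shape[0], n_funcs, N_CLASSES))
        np.put_along_axis(targets, y2[:, :, None], 1.0, axis=2)
        targets = targets.reshape(X.shape[0], -1)

        opt = self._make_optimizer()
        self.loss_history_ = []
        best_metric, best_params = -np.inf, None
        n = X.shape[0]
        for _epoch in range(self.epochs):
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                loss = self._train_step(X[idx], targets[idx], w[idx], opt)
                epoch_loss += loss
                n_batches += 1
            self.loss_history_.append(epoch_loss / n_batches)
            if validation_data is not None:
                Xv, yv = validation_data
                yv = np.asarray(yv)
                yv2 = yv[:, None] if yv.ndim == 1 else yv
                probs = self.predict_frame_distributions(Xv)
                aucs = []
                for f in range(n_funcs):
                    if len(np.unique(yv2[:, f])) >= 2:
                        aucs.append(multiclass_auc(probs[:, f, :], yv2[:, f]))
                if aucs and float(np.mean(aucs)) > best_metric:
                    best_metric = float(np.mean(aucs))
                    best_params = [p.copy() for p in self.net_.params]
        if best_params is not None:
            for p, bp in zip(self.net_.params, best_params):
                p[...] = bp
            self.validation_score_ = best_metric
        return self

    def _make_optimizer(self):
        if self.optimizer == "adam":
            return _nn.Adam(self.net_.params, lr=self.learning_rate)
        if self.optimizer == "sgd":
            return _SGD(self.net_.params, lr=self.learning_rate)
        raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def _train_step(self, Xb, tb, wb, opt) -> float:
        logits = self.net_.forward(Xb, train=True)
        loss, grad = _nn.weighted_bce_with_logits(logits, tb, wb)
        self.net_.backward(grad)
        opt.step(self.net_.grads)
        return loss

    # ---------------------------------------------------------------
    def predict_activations(self, X) -> np.ndarray:
        """Raw per-label sigmoid activations, shape (n, n_functions, 5)."""
        X = self._prepare_X(X)
        n_funcs = len(self.functions_)
        if X.shape[0] == 0:
            return np.empty((0, n_funcs, N_CLASSES))
        outs = []
        for start in range(0, X.shape[0], 256):
            logits = self.net_.forward(X[start : start + 256], train=False)
            outs.append(_nn.sigmoid(logits))
        return np.concatenate(outs).reshape(-1, n_funcs, N_CLASSES)

    def predict_frame_distributions(self, X) -> np.ndarray:
        """Normalized per-function class distributions, shape (n, F, 5)."""
        return _normalize_activations(self.predict_activations(X))

    def predict(self, X) -> np.ndarray:
        """Most probable class per function; shape (n,) or (n, n_functions)."""
        pred = self.predict_frame_distributions(X).argmax(axis=2)
        return pred[:, 0] if len(self.functions_) == 1 else pred


class _SGD:
    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class SpectrogramCNNClassifier(_FrameNetBase, ClassifierMixin):
    """Small 2-D CNN over spectrogram windows.

    A compact VGG-style stack — repeated [3x3 conv, batch norm, ReLU,
    2x2 max pool] blocks with doubling filter counts — followed by global
    average pooling and a dense head emitting 5 sigmoid activations per
    target function.  ``filters`` controls the per-block filter counts so
    larger stacks can be swapped in.  Inputs may be (n, H, W) single-channel
    windows or (n, C, H, W) multi-channel stacks (e.g. 4 limbs).

    Defaults mirror the published voice-model training setup: Adam,
    mini-batch 64, learning rate 1e-5, ~25 epochs.  For the accelerometer
    CNN use ``batch_size=32``.
    """

    def __init__(
        self,
        target_functions=None,
        filters=(8, 16, 32),
        learning_rate: float = 1e-5,
        batch_size: int = 64,
        epochs: int = 25,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        super().__init__(
            target_functions=target_functions,
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            optimizer=optimizer,
            random_state=random_state,
        )
        self.filters = filters

    def _prepare_X(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.ndim != 4:
            raise ValueError("CNN input must be (n, H, W) or (n, C, H, W)")
        return X

    def _build_net(self, input_shape, n_outputs, rng):
        c = input_shape[0]
        layers: list[_nn.Layer] = []
        for f in self.filters:
            layers += [
                _nn.Conv2D(c, f, rng),
                _nn.BatchNorm(f),
                _nn.ReLU(),
                _nn.MaxPool2x2(),
            ]
            c = f
        layers += [_nn.GlobalAvgPool(), _nn.Dense(c, n_outputs, rng)]
        return _nn.Sequential(layers)


class FeatureMLPClassifier(_FrameNetBase, ClassifierMixin):
    """Multi-layer perceptron over 1 Hz feature vectors.

    Defaults mirror the published simple-model setup: batch size 100,
    60 epochs.  Supports single-function and 9-function multi-label heads.
    """

    def __init__(
        self,
        target_functions=None,
        hidden_layer_sizes=(64,),
        learning_rate: float = 1e-3,
        batch_size: int = 100,
        epochs: int = 60,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        super().__init__(
            target_functions=target_functions,
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            optimizer=optimizer,
            random_state=random_state,
        )
        self.hidden_layer_sizes = hidden_layer_sizes

    def _build_net(self, input_shape, n_outputs, rng):
        (n_in,) = input_shape
        layers: list[_nn.Layer] = []
        for h in self.hidden_layer_sizes:
            layers += [_nn.Dense(n_in, h, rng), _nn.ReLU()]
            n_in = h
        layers.append(_nn.Dense(n_in, n_outputs, rng))
        return _nn.Sequential(layers)


class FeatureLogisticClassifier(FeatureMLPClassifier):
    """Logistic regression: one sigmoid per (function, score) label."""

    def __init__(
        self,
        target_functions=None,
        learning_rate: float = 1e-3,
        batch_size: int = 100,
        epochs: int = 60,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        super().__init__(
            target_functions=target_functions,
            hidden_layer_sizes=(),
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            optimizer=optimizer,
            random_state=random_state,
        )

    def get_params(self, deep=True):
        params = super().get_params(deep=deep)
        params.pop("hidden_layer_sizes", None)
        return params


class FeatureLinearRegressor(_FrameNetBase, RegressorMixin):
    """Linear regression on the integer score, squared-error loss.

    ``predict`` returns the continuous score per function.  For AUC
    comparability with the classifiers, ``predict_frame_distributions``
    maps the continuous prediction to a pseudo-distribution over the five
    classes with a distance softmax ``p_k proportional to
    exp(-(k - yhat)^2 / temperature)``; on exact integer predictions its
    argmax reproduces the integer.
    """

    def __init__(
        self,
        target_functions=None,
        learning_rate: float = 1e-3,
        batch_size: int = 100,
        epochs: int = 60,
        optimizer: str = "adam",
        temperature: float = 0.5,
        random_state: int = 0,
    ):
        super().__init__(
            target_functions=target_functions,
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            optimizer=optimizer,
            random_state=random_state,
        )
        self.temperature = temperature

    def _build_net(self, input_shape, n_outputs, rng):
        (n_in,) = input_shape
        # one continuous output per function
        return _nn.Sequential([_nn.Dense(n_in, n_outputs // N_CLASSES, rng)])

    def _train_step(self, Xb, tb, wb, opt) -> float:
        # recover integer targets / per-function weights from the one-hot form
        n_funcs = len(self.functions_)
        t = tb.reshape(len(Xb), n_funcs, N_CLASSES)
        y = t.argmax(axis=2).astype(np.float64)
        w = wb.reshape(len(Xb), n_funcs, N_CLASSES)[:, :, 0]
        preds = self.net_.forward(Xb, train=True)
        loss, grad = _nn.weighted_mse(preds, y, w)
        self.net_.backward(grad)
        opt.step(self.net_.grads)
        return loss

    def predict(self, X) -> np.ndarray:
        """Continuous score per function; shape (n,) or (n, n_functions)."""
        X = self._prepare_X(X)
        if X.shape[0] == 0:
            return np.empty((0, len(self.functions_)))
        out = np.concatenate(
            [
                self.net_.forward(X[s : s + 256], train=False)
                for s in range(0, X.shape[0], 256)
            ]
        )
        return out[:, 0] if len(self.functions_) == 1 else out

    def predict_activations(self, X) -> np.ndarray:
        yhat = np.atleast_2d(self.predict(X))
        if len(self.functions_) == 1:
            yhat = yhat.reshape(-1, 1)
        k = np.arange(N_CLASSES)
        return np.exp(-((k[None, None, :] - yhat[:, :, None]) ** 2) / self.temperature)


# ---------------------------------------------------------------------------
# Config-driven construction (functional surface over the estimators)

_SPECTROGRAM_VARIANTS = ("logmel_voice", "linear_accel")
_FEATURE_VARIANTS = ("fft1hz", "uniform1hz")


@dataclass
class ModelConfig:
    """Declarative model description.

    Defaults per architecture/input mirror the published final training
    hyperparameters: voice CNN batch 64 / lr 1e-5 / 25 epochs; accelerometer
    CNN batch 32 / lr 1e-5; simple models batch 100 / 60 epochs.
    """

    architecture: str = "mlp"            # cnn | mlp | logreg | linreg
    input_variant: str = "fft1hz"        # logmel_voice | linear_accel | fft1hz | uniform1hz
    target_functions: tuple[str, ...] = ("speech",)
    learning_rate: float | None = None
    batch_size: int | None = None
    epochs: int | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.architecture not in ("cnn", "mlp", "logreg", "linreg"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "cnn" and self.input_variant not in _SPECTROGRAM_VARIANTS:
            raise ValueError("cnn pairs only with spectrogram input variants")
        if self.architecture != "cnn" and self.input_variant not in _FEATURE_VARIANTS:
            raise ValueError(
                f"{self.architecture} pairs only with 1 Hz feature variants"
            )
        if self.learning_rate is None:
            self.learning_rate = 1e-5 if self.architecture == "cnn" else 1e-3
        if self.batch_size is None:
            if self.architecture == "cnn":
                self.batch_size = 64 if self.input_variant == "logmel_voice" else 32
            else:
                self.batch_size = 100
        if self.epochs is None:
            self.epochs = 25 if self.architecture == "cnn" else 60


def build_model(config: ModelConfig):
    """Instantiate the estimator described by a ModelConfig."""
    common = dict(
        target_functions=config.target_functions,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        random_state=config.seed,
    )
    if config.architecture == "cnn":
        return SpectrogramCNNClassifier(**common, **config.extra)
    if config.architecture == "mlp":
        return FeatureMLPClassifier(**common, **config.extra)
    if config.architecture == "logreg":
        return FeatureLogisticClassifier(**common, **config.extra)
    return FeatureLinearRegressor(**common, **config.extra)


def train(model, windows, labels, validation_data=None):
    """Fit a frame model; returns (model, per-epoch training loss history)."""
    model = model.fit(windows, labels, validation_data=validation_data)
    return model, list(model.loss_history_)


def predict_frames(model, windows) -> list[FramePrediction]:
    """Per-window FramePredictions from a fitted model."""
    windows = np.asarray(windows, dtype=np.float64)
    if windows.shape[0] == 0:
        return []
    act = model.predict_activations(windows)
    probs = _normalize_activations(act)
    functions = tuple(model.functions_)
    return [FramePrediction(functions, a, p) for a, p in zip(act, probs)]
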