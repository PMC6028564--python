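"""Five small neural-network classifiers implemented from first principles.

These are the base learners of the random NN cluster:

* :class:`BPClassifier` — one-hidden-layer backpropagation network, sigmoid
  hidden units, linear output units, 1-of-K targets, full-batch gradient
  descent on the squared error E = sum_j (c_j - o_j)^2 / 2.
* :class:`PNNClassifier` — probabilistic neural network: a Parzen-window
  Bayes classifier whose pattern units are Gaussian kernels
  exp(-||s - s_ij||^2 / sigma^2) centred on the stored training patterns;
  the class score is the mean kernel activation over that class's patterns
  and the decision is its argmax.
* :class:`CompetitiveClassifier` — winner-take-all competitive layer trained
  by the inner-star rule dw = eta (p - w) for the winning prototype only;
  class labels are attached to prototypes afterwards by majority vote of
  the training samples each prototype wins.
* :class:`LVQClassifier` — learning vector quantization (LVQ1): labelled
  prototypes, winner moved toward a same-label sample and away from a
  different-label sample.
* :class:`ElmanClassifier` — simple recurrent network with a context layer
  that replays the previous hidden state scaled by a delay factor alpha.
  Static feature vectors are presented as a short sequence of contiguous
  feature chunks so the recurrent state has a role.

All estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) and standardize features internally on the training data.
Given the same ``random_state`` and data, fitting is fully deterministic.
Ties in the output argmax go to the lowest class index (the class listed
first in ``classes_``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_X_y

__all__ = [
    "TrainConfig",
    "BPClassifier",
    "PNNClassifier",
    "CompetitiveClassifier",
    "LVQClassifier",
    "ElmanClassifier",
    "BASE_CLASSIFIERS",
    "make_base_classifier",
    "fit_bp",
    "fit_pnn",
    "fit_competitive",
    "fit_lvq",
    "fit_elman",
    "predict",
    "accuracy",
    "model_to_dict",
    "model_from_dict",
]


@dataclass
class TrainConfig:
    """Shared training hyper-parameters for the functional wrappers.

    Fields left as ``None`` fall back to each classifier's own default
    (the per-network defaults differ: the Elman net needs a larger step
    and more epochs than the plain BP net to reach the same training
    error through its recurrent pathway). ``sigma`` (PNN kernel width) of
    ``None`` selects sqrt(d) at fit time, which keeps the kernel
    informative as the sampled feature dimension d changes;
    ``context_decay`` is the Elman delay alpha.
    """

    hidden_units: int = 10
    learning_rate: float | None = None
    epochs: int | None = None
    seed: int = 0
    sigma: float | None = None
    context_decay: float = 1.0
    n_chunks: int = 4
    n_prototypes: int = 2


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class _ScaledNNBase(BaseEstimator, ClassifierMixin):
    """Common plumbing: validation, label coding, standardization."""

    def _validate_fit(self, X, y, min_classes: int = 2):
        X, y = check_X_y(X, y, dtype=float)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < min_classes:
            raise ValueError(
                f"need at least {min_classes} classes, got {len(classes)}"
            )
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return (X - self.mean_) / self.scale_, y_idx

    def _validate_predict(self, X):
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        return (X - self.mean_) / self.scale_

    def predict(self, X):
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


class BPClassifier(_ScaledNNBase):
    """Backpropagation network: sigmoid hidden layer, linear outputs.

    Trained by full-batch gradient descent on the mean per-sample squared
    error sum_j (c_j - o_j)^2 / 2 with 1-of-K target coding c. Weights are
    initialized uniform(-0.5, 0.5) from the seeded generator.

    Attributes
    ----------
    w_hidden_, b_hidden_ : input-to-hidden weights and biases
    w_out_, b_out_ : hidden-to-output weights and biases
    loss_curve_ : training loss after each epoch
    """

    def __init__(self, hidden_units: int = 10, learning_rate: float = 0.3,
                 epochs: int = 500, tol: float = 1e-6,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.tol = tol
        self.random_state = random_state

    def _forward(self, xs):
        h = _sigmoid(xs @ self.w_hidden_.T + self.b_hidden_)
        return h, h @ self.w_out_.T + self.b_out_

    def fit(self, X, y):
        if self.hidden_units < 1 or self.epochs < 1 or self.learning_rate < 0:
            raise ValueError("invalid training configuration")
        xs, y_idx = self._validate_fit(X, y)
        n, m = xs.shape
        k = len(self.classes_)
        targets = np.eye(k)[y_idx]
        rng = np.random.default_rng(self.random_state)
        h = self.hidden_units
        self.w_hidden_ = rng.uniform(-0.5, 0.5, (h, m))
        self.b_hidden_ = rng.uniform(-0.5, 0.5, h)
        self.w_out_ = rng.uniform(-0.5, 0.5, (k, h))
        self.b_out_ = rng.uniform(-0.5, 0.5, k)
        eta = self.learning_rate
        losses = []
        for _ in range(self.epochs):
            hid, out = self._forward(xs)
            err = out - targets                      # d(loss)/d(out), x n
            g_out = err.T @ hid / n
            gb_out = err.mean(axis=0)
            d_hid = (err @ self.w_out_) * hid * (1 - hid)
            g_hid = d_hid.T @ xs / n
            gb_hid = d_hid.mean(axis=0)
            self.w_out_ -= eta * g_out
            self.b_out_ -= eta * gb_out
            self.w_hidden_ -= eta * g_hid
            self.b_hidden_ -= eta * gb_hid
            _, out = self._forward(xs)
            losses.append(0.5 * np.mean(np.sum((targets - out) ** 2, axis=1)))
            if _converged(losses, self.tol):
                break
        self.loss_curve_ = np.asarray(losses)
        return self

    def decision_scores(self, X):
        xs = self._validate_predict(X)
        return self._forward(xs)[1]


#: consecutive epochs with per-epoch loss improvement below tol that end
#: gradient-descent training early
_PATIENCE = 10


def _converged(losses: list, tol: float) -> bool:
    if tol <= 0 or len(losses) < _PATIENCE + 1:
        return False
    recent = np.diff(losses[-(_PATIENCE + 1):])
    return bool(np.all(recent > -tol))


class PNNClassifier(_ScaledNNBase):
    """Probabilistic neural network (Parzen-window Bayes classifier).

    Stores the (standardized) training patterns; the pattern-unit
    activation for query s and stored pattern s_ij is
    ``exp(-||s - s_ij||^2 / sigma^2)`` and the class score is the mean
    activation over the class's patterns. The shared Gaussian
    normalization constant cancels in the argmax and is omitted.

    ``sigma=None`` (default) selects ``sqrt(d)`` at fit time, d being the
    feature dimension, so squared distances — which grow linearly with d
    for standardized features — stay on the kernel's sensitive scale.
    """

    def __init__(self, sigma: float | None = None):
        self.sigma = sigma

    def fit(self, X, y):
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        xs, y_idx = self._validate_fit(X, y)
        self.sigma_ = float(self.sigma) if self.sigma is not None else float(
            np.sqrt(xs.shape[1])
        )
        self.patterns_ = xs
        self.pattern_class_ = y_idx
        return self

    def decision_scores(self, X):
        xs = self._validate_predict(X)
        d2 = cdist(xs, self.patterns_, "sqeuclidean")
        phi = np.exp(-d2 / self.sigma_**2)
        scores = np.empty((xs.shape[0], len(self.classes_)))
        for c in range(len(self.classes_)):
            scores[:, c] = phi[:, self.pattern_class_ == c].mean(axis=1)
        return scores


class CompetitiveClassifier(_ScaledNNBase):
    """Winner-take-all competitive network with post-hoc class labels.

    Training is unsupervised: for each sample the closest prototype wins
    (S = 1) and is moved by the inner-star rule dw = eta (p - w); all other
    prototypes are unchanged (S = 0). Samples are presented in a seeded
    random order each epoch. After training each prototype is assigned the
    majority class label among the training samples it wins; a prototype
    that wins no samples falls back to the overall majority class.
    """

    def __init__(self, n_prototypes: int = 2, learning_rate: float = 0.01,
                 epochs: int = 500, random_state: int = 0):
        self.n_prototypes = n_prototypes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y):
        xs, y_idx = self._validate_fit(X, y, min_classes=1)
        n, m = xs.shape
        if n < 2:
            raise ValueError("competitive training needs at least 2 samples")
        if self.n_prototypes > n:
            raise ValueError(
                f"{self.n_prototypes} prototypes but only {n} samples"
            )
        if self.n_prototypes < 1:
            raise ValueError("n_prototypes must be >= 1")
        rng = np.random.default_rng(self.random_state)
        w = rng.uniform(-0.5, 0.5, (self.n_prototypes, m))
        eta = self.learning_rate
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for idx in order:
                p = xs[idx]
                winner = np.argmin(np.sum((w - p) ** 2, axis=1))
                w[winner] += eta * (p - w[winner])
        self.prototypes_ = w
        # label prototypes by majority vote of the samples they win
        winners = np.argmin(cdist(xs, w, "sqeuclidean"), axis=1)
        overall = np.bincount(y_idx, minlength=len(self.classes_)).argmax()
        labels = np.full(self.n_prototypes, overall)
        for j in range(self.n_prototypes):
            won = y_idx[winners == j]
            if won.size:
                labels[j] = np.bincount(won, minlength=len(self.classes_)).argmax()
        self.prototype_class_ = labels
        return self

    def decision_scores(self, X):
        xs = self._validate_predict(X)
        d2 = cdist(xs, self.prototypes_, "sqeuclidean")
        win = np.argmin(d2, axis=1)
        scores = np.zeros((xs.shape[0], len(self.classes_)))
        scores[np.arange(xs.shape[0]), self.prototype_class_[win]] = 1.0
        return scores


class LVQClassifier(_ScaledNNBase):
    """Learning vector quantization (LVQ1) with labelled prototypes.

    Prototypes start at their class mean (extra prototypes per class get a
    small seeded jitter) and are updated online: the overall winner moves
    toward the sample when the labels match and away otherwise, with step
    eta. With eta = 0 and one prototype per class this is the
    nearest-class-mean classifier.
    """

    def __init__(self, n_prototypes_per_class: int = 1,
                 learning_rate: float = 0.01, epochs: int = 500,
                 random_state: int = 0):
        self.n_prototypes_per_class = n_prototypes_per_class
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_prototypes_per_class < 1:
            raise ValueError("n_prototypes_per_class must be >= 1")
        xs, y_idx = self._validate_fit(X, y)
        n, m = xs.shape
        rng = np.random.default_rng(self.random_state)
        protos, labels = [], []
        for c in range(len(self.classes_)):
            mu = xs[y_idx == c].mean(axis=0)
            for j in range(self.n_prototypes_per_class):
                jitter = 0.0 if j == 0 else rng.normal(0, 0.01, m)
                protos.append(mu + jitter)
                labels.append(c)
        w = np.asarray(protos)
        labels = np.asarray(labels)
        eta = self.learning_rate
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for idx in order:
                p = xs[idx]
                winner = np.argmin(np.sum((w - p) ** 2, axis=1))
                sign = 1.0 if labels[winner] == y_idx[idx] else -1.0
                w[winner] += sign * eta * (p - w[winner])
        self.prototypes_ = w
        self.prototype_class_ = labels
        return self

    def decision_scores(self, X):
        xs = self._validate_predict(X)
        d2 = cdist(xs, self.prototypes_, "sqeuclidean")
        win = np.argmin(d2, axis=1)
        scores = np.zeros((xs.shape[0], len(self.classes_)))
        scores[np.arange(xs.shape[0]), self.prototype_class_[win]] = 1.0
        return scores


class ElmanClassifier(_ScaledNNBase):
    """Elman recurrent network over chunked static feature vectors.

    The m standardized features are split into ``n_chunks`` contiguous
    chunks (zero-padded to equal length) and presented as a short sequence
    e(1)..e(S). The hidden state is

        h(f) = sigmoid(W2 e(f) + W1 (alpha h(f-1)) + b)

    where ``alpha`` (``context_decay``) is the fixed context delay; the
    linear output reads the final hidden state and training is full-batch
    gradient descent (backpropagation through time) on the mean squared
    error M = ||S_d - S||^2 / 2 against 1-of-K targets. With alpha = 0 the
    context layer is silent and the network degenerates to a feed-forward
    net over the last chunk's pathway.
    """

    def __init__(self, hidden_units: int = 10, learning_rate: float = 0.5,
                 epochs: int = 1000, context_decay: float = 1.0,
                 n_chunks: int = 4, tol: float = 1e-6,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.context_decay = context_decay
        self.n_chunks = n_chunks
        self.tol = tol
        self.random_state = random_state

    def _chunk(self, xs):
        n, m = xs.shape
        s = self.n_chunks
        d = -(-m // s)  # ceil
        padded = np.zeros((n, s * d))
        padded[:, :m] = xs
        return [padded[:, t * d:(t + 1) * d] for t in range(s)]

    def _forward(self, chunks):
        n = chunks[0].shape[0]
        alpha = self.context_decay
        h = np.zeros((n, self.hidden_units))
        states = []
        for e_t in chunks:
            h = _sigmoid(e_t @ self.w_in_.T + (alpha * h) @ self.w_ctx_.T
                         + self.b_hidden_)
            states.append(h)
        out = h @ self.w_out_.T + self.b_out_
        return states, out

    def fit(self, X, y):
        if self.hidden_units < 1 or self.epochs < 1 or self.n_chunks < 1:
            raise ValueError("invalid training configuration")
        if not 0.0 <= self.context_decay <= 1.0:
            raise ValueError("context_decay must be in [0, 1]")
        xs, y_idx = self._validate_fit(X, y)
        n, m = xs.shape
        k = len(self.classes_)
        targets = np.eye(k)[y_idx]
        rng = np.random.default_rng(self.random_state)
        hdim = self.hidden_units
        d = -(-m // self.n_chunks)
        self.w_in_ = rng.uniform(-0.5, 0.5, (hdim, d))      # W2
        self.w_ctx_ = rng.uniform(-0.5, 0.5, (hdim, hdim))  # W1
        self.b_hidden_ = rng.uniform(-0.5, 0.5, hdim)
        self.w_out_ = rng.uniform(-0.5, 0.5, (k, hdim))     # W3
        self.b_out_ = rng.uniform(-0.5, 0.5, k)
        chunks = self._chunk(xs)
        alpha = self.context_decay
        eta = self.learning_rate
        losses = []
        for _ in range(self.epochs):
            states, out = self._forward(chunks)
            err = (out - targets) / n
            g_out = err.T @ states[-1]
            gb_out = err.sum(axis=0)
            g_in = np.zeros_like(self.w_in_)
            g_ctx = np.zeros_like(self.w_ctx_)
            gb_h = np.zeros_like(self.b_hidden_)
            dh = err @ self.w_out_
            for t in range(self.n_chunks - 1, -1, -1):
                h_t = states[t]
                da = dh * h_t * (1 - h_t)
                g_in += da.T @ chunks[t]
                h_prev = states[t - 1] if t > 0 else np.zeros_like(h_t)
                g_ctx += da.T @ (alpha * h_prev)
                gb_h += da.sum(axis=0)
                dh = alpha * (da @ self.w_ctx_)
            self.w_out_ -= eta * g_out
            self.b_out_ -= eta * gb_out
            self.w_in_ -= eta * g_in
            self.w_ctx_ -= eta * g_ctx
            self.b_hidden_ -= eta * gb_h
            _, out = self._forward(chunks)
            losses.append(0.5 * np.mean(np.sum((targets - out) ** 2, axis=1)))
            if _converged(losses, self.tol):
                break
        self.loss_curve_ = np.asarray(losses)
        return self

    def decision_scores(self, X):
        xs = self._validate_predict(X)
        return self._forward(self._chunk(xs))[1]


#: registry of base-classifier kinds for the random NN cluster
BASE_CLASSIFIERS = {
    "bp": BPClassifier,
    "pnn": PNNClassifier,
    "competitive": CompetitiveClassifier,
    "lvq": LVQClassifier,
    "elman": ElmanClassifier,
}


def make_base_classifier(kind: str, cfg: TrainConfig | None = None,
                         random_state: int = 0):
    """Instantiate one of the five base classifiers from a TrainConfig."""
    cfg = cfg or TrainConfig()
    common: dict = {}
    if cfg.learning_rate is not None:
        common["learning_rate"] = cfg.learning_rate
    if cfg.epochs is not None:
        common["epochs"] = cfg.epochs
    if kind == "bp":
        return BPClassifier(hidden_units=cfg.hidden_units,
                            random_state=random_state, **common)
    if kind == "pnn":
        return PNNClassifier(sigma=cfg.sigma)
    if kind == "competitive":
        return CompetitiveClassifier(n_prototypes=cfg.n_prototypes,
                                     random_state=random_state, **common)
    if kind == "lvq":
        return LVQClassifier(random_state=random_state, **common)
    if kind == "elman":
        return ElmanClassifier(hidden_units=cfg.hidden_units,
                               context_decay=cfg.context_decay,
                               n_chunks=cfg.n_chunks,
                               random_state=random_state, **common)
    raise ValueError(f"unknown base classifier kind {kind!r}")


def _fit_kind(kind, X, y, cfg):
    cfg = cfg or TrainConfig()
    return make_base_classifier(kind, cfg, random_state=cfg.seed).fit(X, y)


def fit_bp(X, y, cfg: TrainConfig | None = None) -> BPClassifier:
    return _fit_kind("bp", X, y, cfg)


def fit_pnn(X, y, cfg: TrainConfig | None = None) -> PNNClassifier:
    return _fit_kind("pnn", X, y, cfg)


def fit_competitive(X, y, cfg: TrainConfig | None = None) -> CompetitiveClassifier:
    return _fit_kind("competitive", X, y, cfg)


def fit_lvq(X, y, cfg: TrainConfig | None = None) -> LVQClassifier:
    return _fit_kind("lvq", X, y, cfg)


def fit_elman(X, y, cfg: TrainConfig | None = None) -> ElmanClassifier:
    return _fit_kind("elman", X, y, cfg)


def predict(model, X):
    """Uniform prediction entry point for any of the five models."""
    return model.predict(X)


def accuracy(model, X, y) -> float:
    """Fraction of correct predictions, in [0, 1]."""
    y = np.asarray(y)
    pred = model.predict(X)
    if len(pred) != len(y):
        raise ValueError("X and y length mismatch")
    return float(np.mean(pred == y))


_FITTED_ARRAYS = (
    "classes_", "mean_", "scale_", "w_hidden_", "b_hidden_", "w_out_",
    "b_out_", "loss_curve_", "patterns_", "pattern_class_", "prototypes_",
    "prototype_class_", "w_in_", "w_ctx_",
)
_FITTED_SCALARS = ("n_features_in_", "sigma_")


def model_to_dict(model) -> dict:
    """Serialize a fitted model (architecture + weights) to plain types."""
    kind = {v: k for k, v in BASE_CLASSIFIERS.items()}[type(model)]
    state: dict = {"kind": kind, "params": model.get_params()}
    arrays = {}
    for name in _FITTED_ARRAYS:
        if hasattr(model, name):
            arr = np.asarray(getattr(model, name))
            arrays[name] = {"dtype": str(arr.dtype), "data": arr.tolist()}
    scalars = {n: getattr(model, n) for n in _FITTED_SCALARS if hasattr(model, n)}
    state["arrays"] = arrays
    state["scalars"] = scalars
    return state


def model_from_dict(state: dict):
    """Rebuild a fitted model serialized by :func:`model_to_dict`."""
    cls = BASE_CLASSIFIERS[state["kind"]]
    model = cls(**state["params"])
    for name, spec in state["arrays"].items():
        setattr(model, name, np.asarray(spec["data"], dtype=spec["dtype"]))
    for name, val in state["scalars"].items():
        setattr(model, name, val)
    return model
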