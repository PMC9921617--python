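"""Bidirectional LSTM sequence classifier and a linear baseline.

The classifier consumes feature sequences (time steps x feature dim) and
predicts one of two (or more) imagery classes.  Architecture: one
bidirectional LSTM layer, a dropout layer active only during training,
a fully connected readout on the concatenated final hidden states of the
two directions, and a softmax.

Training uses Adam with the schedule the decoder is configured for:
the learning rate at iteration ``k`` (one iteration = one pass over the
training set) is ``initial_learning_rate * lr_decay_factor ** k``, L2
regularisation is applied to all weight matrices, and training stops
after ``max_iterations`` passes.  The readout is initialised at zero, so
under small learning rates the decision boundary's orientation is set by
the accumulated gradient direction rather than by a random
initialisation.  Everything is seeded and single-threaded deterministic.

The :class:`LogisticBaseline` (multinomial logistic regression on
time-averaged features) exposes the same ``fit``/``predict`` contract;
it exists to separate pipeline failures from sequence-model failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "TrainingConfig",
    "SequenceClassifier",
    "LogisticBaseline",
    "evaluate",
]


@dataclass(frozen=True)
class TrainingConfig:
    initial_learning_rate: float = 5e-5
    lr_decay_factor: float = 0.8
    max_iterations: int = 50
    l2_penalty: float = 0.1
    dropout_rate: float = 0.5
    hidden_units: int = 64
    rng_seed: int = 0

    def __post_init__(self):
        if not (
            self.initial_learning_rate > 0
            and self.lr_decay_factor > 0
            and self.max_iterations > 0
            and self.l2_penalty >= 0
            and self.hidden_units > 0
        ):
            raise ValueError("training hyperparameters must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def _init_lstm(rng: np.random.Generator, d: int, h: int) -> dict:
    """Glorot-uniform gate weights; forget-gate bias starts at 1."""
    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0
    return {"Wx": glorot(d, 4 * h), "Wh": glorot(h, 4 * h), "b": b}


def _lstm_forward(X: np.ndarray, p: dict, h_units: int, reverse: bool):
    """Run one direction over the batch; return final hidden and cache."""
    n, T, _ = X.shape
    H = h_units
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    steps = range(T - 1, -1, -1) if reverse else range(T)
    cache = []
    for t in steps:
        x_t = X[:, t]
        z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = expit(z[:, :H])
        f = expit(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = expit(z[:, 3 * H :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        cache.append((x_t, i, f, g, o, c_prev, h_prev, tanh_c))
    return h, cache


def _lstm_backward(dh_final: np.ndarray, cache, p: dict) -> dict:
    """BPTT for one direction given the gradient at the final hidden state."""
    H = dh_final.shape[1]
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for x_t, i, f, g, o, c_prev, h_prev, tanh_c in reversed(cache):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ p["Wh"].T
        dc = dc * f
    return {"Wx": dWx, "Wh": dWh, "b": db}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequenceClassifier:
    """Bidirectional LSTM -> dropout (train only) -> dense -> softmax."""

    def __init__(self, config: TrainingConfig = TrainingConfig()):
        self.config = config
        self.classes_: tuple = ()
        self.params: dict = {}
        self.history: list = []
        self.n_features_: int | None = None
        self.n_steps_: int | None = None

    # ------------------------------------------------------------------ core

    def _forward(self, X: np.ndarray, dropout_mask: np.ndarray | None = None):
        H = self.config.hidden_units
        h_f, cache_f = _lstm_forward(X, self.params["fwd"], H, reverse=False)
        h_b, cache_b = _lstm_forward(X, self.params["bwd"], H, reverse=True)
        u = np.concatenate([h_f, h_b], axis=1)
        if dropout_mask is not None:
            u = u * dropout_mask
        logits = u @ self.params["Wout"] + self.params["bout"]
        return _softmax(logits), (u, cache_f, cache_b, dropout_mask)

    def _loss_and_grads(self, X: np.ndarray, y_idx: np.ndarray, rng=None):
        n = X.shape[0]
        H = self.config.hidden_units
        mask = None
        if rng is not None and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (rng.random((n, 2 * H)) < keep) / keep
        probs, (u, cache_f, cache_b, mask) = self._forward(X, mask)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), y_idx] + eps))

        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        grads = {
            "Wout": u.T @ dlogits,
            "bout": dlogits.sum(axis=0),
        }
        du = dlogits @ self.params["Wout"].T
        if mask is not None:
            du = du * mask
        g_f = _lstm_backward(du[:, :H], cache_f, self.params["fwd"])
        g_b = _lstm_backward(du[:, H:], cache_b, self.params["bwd"])
        for k, v in g_f.items():
            grads[f"fwd.{k}"] = v
        for k, v in g_b.items():
            grads[f"bwd.{k}"] = v

        # coupled L2 on weight matrices (not biases)
        l2 = self.config.l2_penalty
        if l2:
            for name in ("Wout", "fwd.Wx", "fwd.Wh", "bwd.Wx", "bwd.Wh"):
                grads[name] = grads[name] + l2 * self._get(name)
        return loss, grads, probs

    def _get(self, name: str) -> np.ndarray:
        if "." in name:
            scope, key = name.split(".")
            return self.params[scope][key]
        return self.params[name]

    def _set(self, name: str, value: np.ndarray):
        if "." in name:
            scope, key = name.split(".")
            self.params[scope][key] = value
        else:
            self.params[name] = value

    # ------------------------------------------------------------------- api

    def fit(self, sequences: np.ndarray, labels) -> "SequenceClassifier":
        """Train on a stack of equal-length sequences ``(n, T, D)``."""
        X = np.asarray(sequences, dtype=float)
        if X.ndim != 3:
            raise ValueError("sequences must be a 3-D array (n, steps, features)")
        labels = np.asarray(labels)
        classes = tuple(sorted(set(labels.tolist())))
        if len(classes) < 2:
            raise ValueError("need at least two classes to train")
        y_idx = np.array([classes.index(l) for l in labels])
        n, T, D = X.shape
        H = self.config.hidden_units
        K = len(classes)

        rng = np.random.default_rng(self.config.rng_seed)
        self.params = {
            "fwd": _init_lstm(rng, D, H),
            "bwd": _init_lstm(rng, D, H),
            "Wout": np.zeros((2 * H, K)),
            "bout": np.zeros(K),
        }
        self.classes_ = classes
        self.n_features_ = D
        self.n_steps_ = T
        self.history = []

        names = ["Wout", "bout"] + [
            f"{d}.{k}" for d in ("fwd", "bwd") for k in ("Wx", "Wh", "b")
        ]
        m = {nm: np.zeros_like(self._get(nm)) for nm in names}
        v = {nm: np.zeros_like(self._get(nm)) for nm in names}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        cfg = self.config
        for k in range(cfg.max_iterations):
            lr = cfg.initial_learning_rate * cfg.lr_decay_factor**k
            loss, grads, probs = self._loss_and_grads(X, y_idx, rng=rng)
            t = k + 1
            for nm in names:
                g = grads[nm]
                m[nm] = beta1 * m[nm] + (1 - beta1) * g
                v[nm] = beta2 * v[nm] + (1 - beta2) * g**2
                m_hat = m[nm] / (1 - beta1**t)
                v_hat = v[nm] / (1 - beta2**t)
                self._set(nm, self._get(nm) - lr * m_hat / (np.sqrt(v_hat) + eps))
            acc = float(np.mean(probs.argmax(axis=1) == y_idx))
            self.history.append(
                {"iteration": k, "learning_rate": lr, "loss": float(loss),
                 "train_accuracy": acc}
            )
        return self

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        if not self.params:
            raise ValueError("classifier is not fitted")
        X = np.asarray(sequences, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.n_features_:
            raise ValueError(
                f"expected sequences with {self.n_features_} features, got shape {X.shape}"
            )
        probs, _ = self._forward(X, dropout_mask=None)
        return probs[0] if single else probs

    def predict(self, sequences: np.ndarray):
        """Class label(s) and softmax probability array."""
        probs = self.predict_proba(sequences)
        if probs.ndim == 1:
            return self.classes_[int(probs.argmax())], probs
        labels = np.array([self.classes_[i] for i in probs.argmax(axis=1)])
        return labels, probs


class LogisticBaseline:
    """Logistic regression on time-averaged features; same contract as
    :class:`SequenceClassifier`.  Deterministic (lbfgs, fixed seed)."""

    def __init__(self, config: TrainingConfig = TrainingConfig()):
        self.config = config
        self.classes_: tuple = ()
        self._model = LogisticRegression(
            C=1.0 / max(config.l2_penalty, 1e-12), max_iter=1000,
            random_state=config.rng_seed,
        )
        self.n_features_: int | None = None

    @staticmethod
    def _pool(sequences: np.ndarray) -> np.ndarray:
        X = np.asarray(sequences, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return X.mean(axis=1)

    def fit(self, sequences, labels) -> "LogisticBaseline":
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < 2:
            raise ValueError("need at least two classes to train")
        pooled = self._pool(sequences)
        self._model.fit(pooled, labels)
        self.classes_ = tuple(self._model.classes_.tolist())
        self.n_features_ = pooled.shape[1]
        return self

    def predict_proba(self, sequences):
        single = np.asarray(sequences).ndim == 2
        probs = self._model.predict_proba(self._pool(sequences))
        return probs[0] if single else probs

    def predict(self, sequences):
        probs = self.predict_proba(sequences)
        if probs.ndim == 1:
            return self.classes_[int(probs.argmax())], probs
        labels = np.array([self.classes_[i] for i in probs.argmax(axis=1)])
        return labels, probs


def evaluate(model, sequences, labels) -> dict:
    """Accuracy and per-class success rates on a labeled test set."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty test set")
    predicted, _ = model.predict(np.asarray(sequences, dtype=float))
    predicted = np.asarray(predicted)
    correct = predicted == labels
    per_class = {}
    for cls in sorted(set(labels.tolist())):
        sel = labels == cls
        per_class[cls] = float(np.mean(correct[sel]))
    return {"accuracy": float(np.mean(correct)), "per_class": per_class,
            "n": int(labels.size)}
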