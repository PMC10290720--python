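"""Pluggable classifier behind the trainer's handle contract.

A handle owns opaque parameters and supports exactly: ``fit_hard`` (integer
labels), ``fit_soft`` (probability-vector targets), ``predict_proba``,
``clone``, and bit-exact serialization. Training never mutates the handle
it is called on; it returns a freshly trained copy, which keeps federated
round logic purely functional.

The reference implementation is a softmax-regression / one-hidden-layer
tanh network trained by minibatch SGD on (soft-target) cross-entropy. It
is small on purpose: desk-scale federated simulations run thousands of
fits, and an 8-feature Gaussian-mixture task does not need more capacity.
Any model exposing the same five methods can be dropped in.
"""

from __future__ import annotations

import io
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import softmax

__all__ = ["ClassifierHandle", "MLPClassifier"]

_BATCH_SIZE = 32


@runtime_checkable
class ClassifierHandle(Protocol):
    """Contract every trainable classifier must satisfy."""

    n_classes: int
    n_features: int

    def fit_hard(
        self, features: np.ndarray, labels: np.ndarray, epochs: int, lr: float,
        rng: np.random.Generator,
    ) -> "ClassifierHandle": ...

    def fit_soft(
        self, features: np.ndarray, targets: np.ndarray, epochs: int, lr: float,
        rng: np.random.Generator,
    ) -> "ClassifierHandle": ...

    def predict_proba(self, features: np.ndarray) -> np.ndarray: ...

    def clone(self) -> "ClassifierHandle": ...

    def to_bytes(self) -> bytes: ...


class MLPClassifier:
    """Softmax classifier with an optional single tanh hidden layer.

    ``hidden=0`` gives plain multinomial logistic regression. Parameters
    are float64; all stochasticity (init, minibatch shuffling) flows
    through explicitly passed generators, so identical seeds give
    bit-identical models.
    """

    def __init__(self, n_features: int, n_classes: int, hidden: int = 0,
                 params: list[np.ndarray] | None = None):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden = hidden
        if params is not None:
            self._params = [np.array(p, dtype=np.float64) for p in params]
        elif hidden == 0:
            self._params = [np.zeros((n_features + 1, n_classes))]
        else:
            self._params = [
                np.zeros((n_features + 1, hidden)),
                np.zeros((hidden + 1, n_classes)),
            ]

    # -- construction -------------------------------------------------------

    @classmethod
    def create(cls, n_features: int, n_classes: int, rng: np.random.Generator,
               hidden: int = 0) -> "MLPClassifier":
        """Randomly initialized model (Xavier-style per-layer Gaussian weights)."""
        model = cls(n_features, n_classes, hidden)
        model._params = [
            rng.normal(0.0, 1.0 / np.sqrt(p.shape[0]), size=p.shape) for p in model._params
        ]
        return model

    def clone(self) -> "MLPClassifier":
        return MLPClassifier(self.n_features, self.n_classes, self.hidden,
                             params=self._params)

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _with_bias(x: np.ndarray) -> np.ndarray:
        return np.concatenate([x, np.ones((len(x), 1))], axis=1)

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if self.hidden == 0:
            return self._with_bias(x) @ self._params[0], None
        h = np.tanh(self._with_bias(x) @ self._params[0])
        return self._with_bias(h) @ self._params[1], h

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        logits, _ = self._forward(features)
        return softmax(logits, axis=1)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Argmax class per row; ties broken toward the lowest index."""
        return np.argmax(self.predict_proba(features), axis=1)

    def _step(self, x: np.ndarray, t: np.ndarray, lr: float) -> None:
        n = len(x)
        logits, h = self._forward(x)
        delta = (softmax(logits, axis=1) - t) / n  # dCE/dlogits
        if self.hidden == 0:
            self._params[0] -= lr * (self._with_bias(x).T @ delta)
            return
        hb = self._with_bias(h)
        grad2 = hb.T @ delta
        back = (delta @ self._params[1][:-1].T) * (1.0 - h**2)
        grad1 = self._with_bias(x).T @ back
        self._params[1] -= lr * grad2
        self._params[0] -= lr * grad1

    def _fit(self, features: np.ndarray, targets: np.ndarray, epochs: int,
             lr: float, rng: np.random.Generator) -> "MLPClassifier":
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        targets = np.asarray(targets, dtype=np.float64)
        model = self.clone()
        n = len(features)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, _BATCH_SIZE):
                batch = order[start : start + _BATCH_SIZE]
                model._step(features[batch], targets[batch], lr)
        return model

    def fit_soft(self, features: np.ndarray, targets: np.ndarray, epochs: int,
                 lr: float, rng: np.random.Generator) -> "MLPClassifier":
        """Minibatch SGD on soft-target cross-entropy; returns a new handle."""
        targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
        if targets.shape[1] != self.n_classes:
            raise ValueError("target width differs from n_classes")
        return self._fit(features, targets, epochs, lr, rng)

    def fit_hard(self, features: np.ndarray, labels: np.ndarray, epochs: int,
                 lr: float, rng: np.random.Generator) -> "MLPClassifier":
        """Minibatch SGD on one-hot cross-entropy; returns a new handle."""
        labels = np.asarray(labels, dtype=np.int64)
        onehot = np.eye(self.n_classes)[labels]
        return self._fit(features, onehot, epochs, lr, rng)

    def soft_loss(self, features: np.ndarray, targets: np.ndarray) -> float:
        """Mean cross-entropy against soft targets (diagnostic)."""
        probs = self.predict_proba(features)
        return float(-(np.asarray(targets) * np.log(probs + 1e-300)).sum(axis=1).mean())

    # -- flat parameter view (for parameter-averaging baselines) ------------

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self._params)

    def params_vector(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self._params])

    def with_params_vector(self, flat: np.ndarray) -> "MLPClassifier":
        out = self.clone()
        offset = 0
        for i, p in enumerate(out._params):
            out._params[i] = flat[offset : offset + p.size].reshape(p.shape).copy()
            offset += p.size
        return out

    # -- serialization ------------------------------------------------------

    def to_bytes(self) -> bytes:
        buf = io.BytesIO()
        meta = np.array([self.n_features, self.n_classes, self.hidden], dtype=np.int64)
        np.savez(buf, meta=meta, *self._params)
        return buf.getvalue()

    @classmethod
    def from_bytes(cls, raw: bytes) -> "MLPClassifier":
        with np.load(io.BytesIO(raw)) as archive:
            meta = archive["meta"]
            params = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
        return cls(int(meta[0]), int(meta[1]), int(meta[2]), params=params)
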