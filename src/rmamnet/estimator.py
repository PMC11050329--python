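"""scikit-learn estimator wrapping the attention CNN and its training loop.

:class:`RMAMNetClassifier` follows the sklearn contract (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``; fitted attributes carry a
trailing underscore) over feature arrays of shape (N, channels, length) —
the (N, 80, 301) log-Mel matrices under the defaults.  Training minimises
cross-entropy with Adam over shuffled mini-batches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import column_or_1d

from .autodiff import Tensor, softmax_cross_entropy
from .network import NetworkSpec, RMAMNet

__all__ = ["Adam", "RMAMNetClassifier"]


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class RMAMNetClassifier(ClassifierMixin, BaseEstimator):
    """Residual mixed-domain attention CNN for vibration-signal features.

    Parameters
    ----------
    spec:
        Architecture description; ``None`` uses the default 10-layer stack
        (input channels inferred from the data).
    epochs, batch_size, learning_rate:
        Training-loop settings.  The published run used batch 512 for 12
        epochs on ~10k segments; the desk default batch is 32 so small
        synthetic corpora still yield several updates per epoch.
    random_state:
        Seeds parameter initialisation and batch shuffling.

    Attributes
    ----------
    model_ : RMAMNet
        The fitted network.
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    loss_history_ : list of float
        Mean training cross-entropy per epoch.
    """

    def __init__(self, spec: NetworkSpec | None = None, epochs: int = 12,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 warm_start: bool = False, random_state: int | None = None,
                 verbose: int = 0):
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.warm_start = warm_start
        self.random_state = random_state
        self.verbose = verbose

    # -- sklearn plumbing --------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(
                f"X must have shape (n_samples, channels, length); got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "this RMAMNetClassifier instance is not fitted yet; call fit first"
            )

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        X = self._validate_X(X)
        y = column_or_1d(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes to fit a classifier")

        rng = np.random.default_rng(self.random_state)
        resuming = self.warm_start and hasattr(self, "model_")
        if resuming:
            # Continue from the stored epoch counter up to self.epochs total.
            epochs_left = self.epochs - len(self.loss_history_)
            if epochs_left <= 0:
                return self
        else:
            spec = self.spec if self.spec is not None else NetworkSpec(
                in_channels=X.shape[1], n_classes=int(self.classes_.size)
            )
            if spec.in_channels != X.shape[1]:
                raise ValueError(
                    f"network expects {spec.in_channels} input channels, data has {X.shape[1]}"
                )
            if spec.n_classes != self.classes_.size:
                raise ValueError(
                    f"network has {spec.n_classes} output classes, data has {self.classes_.size}"
                )
            self.spec_ = spec
            self.model_ = RMAMNet(spec, rng=rng)
            self.loss_history_ = []
            epochs_left = self.epochs
        self.n_features_in_ = X.shape[1]

        optimizer = Adam(self.model_.parameters(), lr=self.learning_rate)
        n = X.shape[0]
        # lr = 0 is a true no-op: keep eval mode so batch-norm running
        # statistics stay frozen as well.
        self.model_.train(self.learning_rate != 0.0)
        for epoch in range(epochs_left):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2:
                    continue  # batch statistics need >= 2 samples
                loss, _ = softmax_cross_entropy(
                    self.model_(Tensor(X[idx])), y_idx[idx]
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        "training loss became non-finite; try a smaller learning_rate"
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            mean_loss = float(np.mean(losses)) if losses else float("nan")
            self.loss_history_.append(mean_loss)
            if self.verbose:
                print(f"epoch {len(self.loss_history_)}/{self.epochs}: loss {mean_loss:.4f}")
        self.model_.eval()
        return self

    # -- inference ---------------------------------------------------------

    def _batched(self, X: np.ndarray, fn, width: int):
        out = np.empty((X.shape[0], width), dtype=np.float32)
        bs = max(self.batch_size, 1)
        for start in range(0, X.shape[0], bs):
            out[start : start + bs] = fn(Tensor(X[start : start + bs]))
        return out

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        self.model_.eval()
        return self._batched(
            X, self.model_.predict_proba, int(self.classes_.size)
        ).astype(np.float64)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def gap_features(self, X) -> np.ndarray:
        """Penultimate (global-average-pooled) feature vectors, shape (N, 256)."""
        self._check_fitted()
        X = self._validate_X(X)
        self.model_.eval()
        return self._batched(
            X, lambda t: self.model_.features(t).data, self.spec_.final_conv_channels
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise architecture + weights to an ``.npz`` checkpoint."""
        self._check_fitted()
        meta = {
            "spec": self.spec_.to_dict(),
            "classes": self.classes_.tolist(),
            "params": self.get_params(deep=False) | {"spec": None},
            "loss_history": self.loss_history_,
            "epochs_completed": len(self.loss_history_),
        }
        state = self.model_.state_dict()
        np.savez(Path(path), __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path: str | Path) -> "RMAMNetClassifier":
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        clf = cls(**meta["params"])
        clf.spec_ = NetworkSpec.from_dict(meta["spec"])
        clf.model_ = RMAMNet(clf.spec_)
        clf.model_.load_state_dict(state)
        clf.model_.eval()
        clf.classes_ = np.asarray(meta["classes"])
        clf.loss_history_ = list(meta["loss_history"])
        clf.n_features_in_ = clf.spec_.in_channels
        return clf
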