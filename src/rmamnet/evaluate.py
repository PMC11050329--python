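"""Evaluation report: accuracy, macro F1, confusion matrix, 2-D embedding.

Accuracy is reported as a percentage; F1 is macro-averaged (the unweighted
mean of per-class F1), matching the per-class confusion-matrix
presentation.  A class absent from the test set gets F1 = 0 with a
warning.  The 2-D embedding applies t-SNE to the network's 256-dimensional
global-average-pooled feature vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

__all__ = ["EvalReport", "evaluate", "evaluate_predictions", "embed_2d"]


@dataclass
class EvalReport:
    accuracy: float  # percent
    macro_f1: float  # in [0, 1]
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray  # (n_classes, n_classes) ints, rows = true labels
    n_test: int
    labels: list = field(default_factory=list)
    embedding: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
            "labels": [int(l) if isinstance(l, (int, np.integer)) else l for l in self.labels],
        }
        if self.embedding is not None:
            d["embedding"] = self.embedding.tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(y_true, y_pred, labels=None) -> EvalReport:
    """Build an :class:`EvalReport` from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    missing = [l for l in labels if l not in y_true]
    if missing:
        warnings.warn(
            f"classes {missing} absent from the test set; their F1 is defined as 0",
            stacklevel=2,
        )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled via zero_division=0
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    per_class = {
        str(l): {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for l, p, r, f, s in zip(labels, prec, rec, f1, support)
    }
    n = int(y_true.size)
    return EvalReport(
        accuracy=100.0 * float(np.trace(cm)) / n,
        macro_f1=float(np.mean(f1)),
        per_class=per_class,
        confusion=cm,
        n_test=n,
        labels=list(labels),
    )


def evaluate(clf, X_test, y_test, labels=None) -> EvalReport:
    """Evaluate a fitted classifier on test features."""
    if labels is None:
        labels = getattr(clf, "classes_", None)
    return evaluate_predictions(np.asarray(y_test), clf.predict(X_test), labels=labels)


def embed_2d(clf, X, random_state: int | None = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding of the penultimate feature vectors, shape (N, 2).

    Perplexity is auto-reduced (with a warning) when fewer points than the
    t-SNE constraint allows are given.
    """
    feats = clf.gap_features(X)
    n = feats.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 segments for an embedding, got {n}")
    max_perp = (n - 1) / 3.0
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} points; reduced to {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=random_state, init="pca")
    coords = tsne.fit_transform(feats.astype(np.float64))
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("non-finite embedding coordinates")
    return coords


def plot_confusion(report: EvalReport, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    ax.set_xticks(range(len(report.labels)), [str(l) for l in report.labels])
    ax.set_yticks(range(len(report.labels)), [str(l) for l in report.labels])
    for i in range(report.confusion.shape[0]):
        for j in range(report.confusion.shape[1]):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(coords: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for label in np.unique(labels):
        mask = labels == label
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, label=str(label))
    ax.legend(title="class")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
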