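"""Bag-of-n-grams linear classifier (one-vs-rest margin machine).

Sentences are mapped to sparse unigram+bigram count vectors; one
separating hyperplane per class is fit one-vs-rest with a linear SVM,
and the signed margins are calibrated to the probability simplex with a
softmax.  The sentence embedding is the l2-normalized count vector sent
through a seeded Gaussian random projection to ``hidden_size`` dims.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import LinearSVC

from ..labels import CLASS_INDEX, CLASS_ORDER
from .config import ModelConfig, PredictionScore, score_from_vector

__all__ = ["featurize_ngrams", "build_vectorizer", "LinearNgramModel"]

_TOKEN_PATTERN = r"[a-z0-9]+"

#: margin assigned to a class absent from the training data
_ABSENT_MARGIN = -8.0


def build_vectorizer(ngram_orders: Sequence[int] = (1, 2),
                     vocabulary: dict | None = None) -> CountVectorizer:
    orders = sorted(set(ngram_orders))
    return CountVectorizer(
        lowercase=True, token_pattern=_TOKEN_PATTERN,
        ngram_range=(orders[0], orders[-1]), vocabulary=vocabulary)


def featurize_ngrams(
    texts: Sequence[str], ngram_orders: Sequence[int] = (1, 2),
    vocabulary: dict | None = None,
) -> tuple[sp.csr_matrix, dict[str, int]]:
    """Sparse n-gram count matrix plus the vocabulary used.

    When ``vocabulary`` is None it is built from ``texts`` (training
    mode); otherwise counts are restricted to it and unseen n-grams are
    ignored (prediction mode).  An empty vocabulary raises.
    """
    vec = build_vectorizer(ngram_orders, vocabulary)
    if vocabulary is None:
        try:
            X = vec.fit_transform(texts)
        except ValueError as exc:
            raise ValueError(f"empty n-gram vocabulary: {exc}") from None
        return X, vec.vocabulary_
    return vec.transform(texts), dict(vocabulary)


def _softmax(m: np.ndarray) -> np.ndarray:
    z = m - m.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LinearNgramModel:
    """Trained linear kind; weights are plain arrays, portable to disk."""

    kind = "linear_ngram"

    def __init__(self, config: ModelConfig, vocabulary: dict[str, int],
                 W: np.ndarray, b: np.ndarray, projection: np.ndarray):
        self.config = config
        self.vocabulary = vocabulary
        self.W = W  # (n_features, 3) stacked one-vs-rest hyperplanes
        self.b = b  # (3,)
        self.projection = projection  # (n_features, hidden_size)

    # -- training ----------------------------------------------------------

    @classmethod
    def fit(cls, config: ModelConfig, texts: Sequence[str],
            labels: Sequence) -> "LinearNgramModel":
        y = np.array([CLASS_INDEX[lab] for lab in labels])
        if len(set(y.tolist())) < 2:
            raise ValueError("training data contains a single class; "
                             "need examples of at least 2 classes")
        X, vocab = featurize_ngrams(texts, config.ngram_orders)
        n_features = X.shape[1]
        W = np.zeros((n_features, 3))
        b = np.zeros(3)
        for c in range(3):
            yc = (y == c).astype(int)
            if yc.min() == yc.max():  # class absent (or universal): fixed margin
                b[c] = _ABSENT_MARGIN if yc.max() == 0 else -_ABSENT_MARGIN
                continue
            svc = LinearSVC(C=config.svm_c, class_weight="balanced",
                            random_state=config.seed, max_iter=20000)
            svc.fit(X, yc)
            W[:, c] = svc.coef_.ravel()
            b[c] = float(svc.intercept_.ravel()[0])
        rng = np.random.default_rng(config.seed)
        projection = rng.standard_normal((n_features, config.hidden_size))
        projection /= np.sqrt(config.hidden_size)
        return cls(config, vocab, W, b, projection)

    # -- inference ---------------------------------------------------------

    def margins(self, texts: Sequence[str]) -> np.ndarray:
        X, _ = featurize_ngrams(texts, self.config.ngram_orders, self.vocabulary)
        return np.asarray(X @ self.W) + self.b

    def predict(self, texts: Sequence[str]) -> list[PredictionScore]:
        X, _ = featurize_ngrams(texts, self.config.ngram_orders, self.vocabulary)
        margins = np.asarray(X @ self.W) + self.b
        scores = _softmax(margins)
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        emb = (X.multiply(1.0 / norms[:, None])) @ self.projection
        emb = np.asarray(emb)
        return [score_from_vector(scores[i], emb[i]) for i in range(len(texts))]

    # -- fine-tuning -------------------------------------------------------

    def fine_tune(self, texts: Sequence[str], labels: Sequence,
                  max_epochs: int | None = None) -> "LinearNgramModel":
        """Subgradient descent on the one-vs-rest hinge losses, warm-started
        from the current hyperplanes at a reduced learning rate."""
        epochs = self.config.max_epochs if max_epochs is None else max_epochs
        out = LinearNgramModel(self.config, dict(self.vocabulary),
                               self.W.copy(), self.b.copy(),
                               self.projection.copy())
        if epochs == 0:
            return out
        if not texts:
            raise ValueError("fine_tune requires at least one labeled sentence")
        y = np.array([CLASS_INDEX[lab] for lab in labels])
        X, _ = featurize_ngrams(texts, self.config.ngram_orders, self.vocabulary)
        lr = self.config.learning_rate * self.config.finetune_lr_factor
        rng = np.random.default_rng(self.config.seed + 1)
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for i in order:
                xi = X[i]
                for c in range(3):
                    sign = 1.0 if y[i] == c else -1.0
                    margin = sign * (float(xi @ out.W[:, c]) + out.b[c])
                    if margin < 1.0:  # hinge active
                        out.W[:, c] += lr * sign * np.asarray(xi.todense()).ravel()
                        out.b[c] += lr * sign
        return out

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(
            {**self.config.__dict__, "kind": self.kind}, default=list))
        (directory / "vocab.json").write_text(json.dumps(self.vocabulary))
        np.savez(directory / "weights.npz", W=self.W, b=self.b,
                 projection=self.projection)

    @classmethod
    def load(cls, directory: str | Path, config: ModelConfig) -> "LinearNgramModel":
        directory = Path(directory)
        vocab = json.loads((directory / "vocab.json").read_text())
        arrays = np.load(directory / "weights.npz")
        return cls(config, vocab, arrays["W"], arrays["b"], arrays["projection"])
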