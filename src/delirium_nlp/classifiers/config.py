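"""Classifier configuration and the prediction-score contract."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..labels import CLASS_ORDER, Label

MODEL_KINDS = ("linear_ngram", "recurrent", "attention")

#: lowercase alphanumeric-run tokenization, shared by every model kind
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lowercase alphanumeric-run tokens with half-open char spans."""
    return [(m.group(), m.start(), m.end())
            for m in _TOKEN_RE.finditer(text.lower())]


@dataclass
class ModelConfig:
    """Hyperparameters for the three sentence-classifier kinds.

    ``layers`` and ``hidden_size`` apply to the neural kinds (recurrent,
    attention); ``ngram_orders`` to the linear kind.  ``init_vectors``
    optionally points to a word2vec-format text file used to initialize
    the embedding table; the default is seeded random initialization.
    """

    model_kind: str = "linear_ngram"
    layers: int = 3
    hidden_size: int = 128
    ngram_orders: tuple[int, ...] = (1, 2)
    max_epochs: int = 10
    learning_rate: float = 2e-3
    batch_size: int = 64
    seed: int = 0
    init_vectors: Optional[str] = None
    n_heads: int = 4
    max_len: int = 128
    finetune_lr_factor: float = 0.1
    svm_c: float = 1.0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}, "
                             f"got {self.model_kind!r}")
        if self.layers < 1 or self.hidden_size < 2:
            raise ValueError("layers >= 1 and hidden_size >= 2 required")
        orders = tuple(sorted(set(int(o) for o in self.ngram_orders)))
        if any(o < 1 for o in orders):
            raise ValueError("ngram orders must be positive")
        self.ngram_orders = orders
        if self.model_kind in ("recurrent", "attention"):
            if self.hidden_size % (2 * self.n_heads) != 0:
                raise ValueError("hidden_size must be divisible by "
                                 "2 * n_heads for neural kinds")


@dataclass(frozen=True)
class PredictionScore:
    """Per-class score triple on the simplex plus a sentence embedding.

    ``predicted_label`` is the argmax class; ties resolve in the fixed
    order POSITIVE < NEGATIVE < NEITHER.
    """

    scores: np.ndarray
    predicted_label: Label
    embedding: np.ndarray = field(repr=False)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (3,):
            raise ValueError("scores must be a length-3 vector")
        if s.min() < -1e-9 or abs(s.sum() - 1.0) > 1e-6:
            raise ValueError("scores must lie on the probability simplex")
        object.__setattr__(self, "scores", s)
        if CLASS_ORDER[int(np.argmax(s))] is not self.predicted_label:
            raise ValueError("predicted_label inconsistent with argmax")


def score_from_vector(scores: np.ndarray, embedding: np.ndarray) -> PredictionScore:
    scores = np.asarray(scores, dtype=float)
    return PredictionScore(
        scores=scores,
        predicted_label=CLASS_ORDER[int(np.argmax(scores))],
        embedding=np.asarray(embedding, dtype=float),
    )
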