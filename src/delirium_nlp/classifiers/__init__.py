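"""Three keyword-anchored 3-class sentence classifiers.

Model kinds
-----------
``linear_ngram``
    One-vs-rest linear SVM over a bag of unigrams and bigrams; signed
    margins to the three hyperplanes are softmax-calibrated to scores.
``recurrent``
    3-layer bidirectional LSTM; classifies from the hidden vector at the
    delirium-keyword position.
``attention``
    3-layer multi-head self-attention encoder; likewise classifies from
    the keyword-anchor vector.

All kinds emit a :class:`PredictionScore` per sentence: a simplex score
triple over (POSITIVE, NEGATIVE, NEITHER), the argmax label, and a
fixed-length sentence embedding used by the active-learning map.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from ..corpus import Sentence
from ..patterns import LabeledSentence
from .config import ModelConfig, PredictionScore, tokenize
from .linear import LinearNgramModel, featurize_ngrams
from .nets import NeuralModel

__all__ = [
    "ModelConfig", "PredictionScore", "tokenize", "featurize_ngrams",
    "LinearNgramModel", "NeuralModel", "Model",
    "train", "predict", "fine_tune", "save_model", "load_model",
]

Model = Union[LinearNgramModel, NeuralModel]


def train(config: ModelConfig, labeled: Sequence[LabeledSentence]) -> Model:
    """Fit a classifier of ``config.model_kind`` on labeled sentences.

    Requires examples of at least two classes; training is reproducible
    given ``config.seed``.
    """
    if not labeled:
        raise ValueError("no labeled sentences to train on")
    labels = [ls.label for ls in labeled]
    if config.model_kind == "linear_ngram":
        return LinearNgramModel.fit(config,
                                    [ls.sentence.text for ls in labeled], labels)
    return NeuralModel.fit(config, [ls.sentence for ls in labeled], labels)


def predict(model: Model, sentences: Sequence[Sentence]) -> list[PredictionScore]:
    """One :class:`PredictionScore` per sentence, in batch order.

    The neural kinds require a keyword anchor on every sentence; the
    linear kind accepts keyword-free sentences too.
    """
    if isinstance(model, LinearNgramModel):
        return model.predict([s.text for s in sentences])
    return model.predict(sentences)


def fine_tune(model: Model, new_labeled: Sequence[LabeledSentence],
              max_epochs: int | None = None) -> Model:
    """Continue optimization on new labels at a reduced learning rate.

    Returns a new model and leaves ``model`` unchanged; ``max_epochs=0``
    returns an identical copy.
    """
    if not new_labeled:
        raise ValueError("fine_tune requires at least one labeled sentence")
    labels = [ls.label for ls in new_labeled]
    if isinstance(model, LinearNgramModel):
        return model.fine_tune([ls.sentence.text for ls in new_labeled],
                               labels, max_epochs=max_epochs)
    return model.fine_tune([ls.sentence for ls in new_labeled], labels,
                           max_epochs=max_epochs)


def save_model(model: Model, directory: str | Path) -> None:
    model.save(directory)


def load_model(directory: str | Path) -> Model:
    directory = Path(directory)
    raw = json.loads((directory / "config.json").read_text())
    kind = raw.pop("kind")
    raw.pop("model_kind", None)
    raw["ngram_orders"] = tuple(raw.get("ngram_orders", (1, 2)))
    config = ModelConfig(model_kind=kind, **raw)
    if kind == "linear_ngram":
        return LinearNgramModel.load(directory, config)
    return NeuralModel.load(directory, config)
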