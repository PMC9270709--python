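"""Keyword-anchored neural sentence classifiers.

Two model kinds share one training harness:

* ``recurrent`` — a 3-layer bidirectional LSTM encoder; the hidden
  vectors at the delirium-keyword position (first lexicon match,
  mean-pooled over its token span) feed a linear classification head.
* ``attention`` — a 3-layer multi-head self-attention (transformer)
  encoder with sinusoidal positions; classification again reads the
  keyword-anchor vector.

Both run on the in-package autodiff core (float64 NumPy, single
threaded), trained with Adam on class-weighted cross-entropy.  Training
and prediction are deterministic given the config seed.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ..corpus import Sentence
from ..labels import CLASS_INDEX
from . import _autodiff as ad
from .config import ModelConfig, PredictionScore, score_from_vector, tokenize

__all__ = ["NeuralModel", "build_vocab", "encode_batch"]

PAD, UNK = 0, 1


def build_vocab(texts: Sequence[str]) -> dict[str, int]:
    """Token -> id map from training text; ids 0/1 reserved for pad/unk."""
    vocab: dict[str, int] = {"<pad>": PAD, "<unk>": UNK}
    for text in texts:
        for tok, _, _ in tokenize(text):
            vocab.setdefault(tok, len(vocab))
    return vocab


def _anchor_token_indices(sent: Sentence, tokens) -> list[int]:
    """Token positions overlapping the first keyword match (the anchor)."""
    if not sent.matches:
        raise ValueError(
            f"sentence {sent.key} has no keyword match; the neural kinds "
            "need a keyword anchor position")
    m = sent.matches[0]
    idx = [i for i, (_, s, e) in enumerate(tokens) if s < m.end and e > m.start]
    if not idx:  # match span holds no alphanumeric token (cannot normally happen)
        raise ValueError(f"keyword span of sentence {sent.key} holds no token")
    return idx


def encode_batch(
    sentences: Sequence[Sentence], vocab: dict[str, int], max_len: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad/encode sentences: (ids, mask, anchor_pool) arrays.

    ``anchor_pool`` is (B, 1, T) with mean-pooling weights over the
    anchor token span.  Right truncation to ``max_len`` never cuts the
    anchor: when the anchor lies beyond the limit the window is shifted
    left to end at the anchor.
    """
    rows: list[list[int]] = []
    anchors: list[list[int]] = []
    for sent in sentences:
        tokens = tokenize(sent.text)
        if not tokens:
            raise ValueError(f"sentence {sent.key} has no tokens")
        idx = _anchor_token_indices(sent, tokens)
        if len(tokens) > max_len:
            offset = max(0, idx[-1] - max_len + 1)
            tokens = tokens[offset:offset + max_len]
            idx = [i - offset for i in idx if 0 <= i - offset < max_len]
        rows.append([vocab.get(tok, UNK) for tok, _, _ in tokens])
        anchors.append(idx)
    T = max(len(r) for r in rows)
    B = len(rows)
    ids = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T))
    pool = np.zeros((B, 1, T))
    for i, (row, idx) in enumerate(zip(rows, anchors)):
        ids[i, :len(row)] = row
        mask[i, :len(row)] = 1.0
        pool[i, 0, idx] = 1.0 / len(idx)
    return ids, mask, pool


def _sinusoidal_positions(T: int, D: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    dim = np.arange(D // 2)[None, :]
    angle = pos / (10000.0 ** (2 * dim / D))
    out = np.zeros((T, D))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


class NeuralModel:
    """A trained recurrent or attention sentence classifier."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int],
                 params: dict[str, ad.Tensor]):
        self.config = config
        self.vocab = vocab
        self.params = params

    kind = property(lambda self: self.config.model_kind)

    # -- initialization ----------------------------------------------------

    @classmethod
    def init(cls, config: ModelConfig, vocab: dict[str, int]) -> "NeuralModel":
        rng = np.random.default_rng(config.seed)
        H = config.hidden_size
        Hd = H // 2

        def glorot(*shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return ad.parameter(rng.uniform(-lim, lim, size=shape))

        params: dict[str, ad.Tensor] = {
            "embed": ad.parameter(rng.normal(0.0, 0.1, size=(len(vocab), H))),
            "Wout": glorot(H, 3),
            "bout": ad.parameter(np.zeros(3)),
        }
        if config.model_kind == "recurrent":
            for l in range(config.layers):
                in_dim = H  # embeddings and bi-outputs are both H wide
                for d in ("f", "b"):
                    params[f"Wx{l}{d}"] = glorot(in_dim, 4 * Hd)
                    params[f"Wh{l}{d}"] = glorot(Hd, 4 * Hd)
                    bias = np.zeros(4 * Hd)
                    bias[Hd:2 * Hd] = 1.0  # forget-gate bias
                    params[f"b{l}{d}"] = ad.parameter(bias)
        else:  # attention
            for l in range(config.layers):
                for name in ("Wq", "Wk", "Wv", "Wo"):
                    params[f"{name}{l}"] = glorot(H, H)
                params[f"W1_{l}"] = glorot(H, 2 * H)
                params[f"b1_{l}"] = ad.parameter(np.zeros(2 * H))
                params[f"W2_{l}"] = glorot(2 * H, H)
                params[f"b2_{l}"] = ad.parameter(np.zeros(H))
                for ln in ("ln1", "ln2"):
                    params[f"{ln}g{l}"] = ad.parameter(np.ones(H))
                    params[f"{ln}b{l}"] = ad.parameter(np.zeros(H))
        model = cls(config, vocab, params)
        if config.init_vectors:
            model._load_init_vectors(config.init_vectors)
        return model

    def _load_init_vectors(self, path: str) -> None:
        """Seed embedding rows from a word2vec-format text file."""
        H = self.config.hidden_size
        table = self.params["embed"].data
        for line in Path(path).read_text().splitlines():
            parts = line.rstrip().split(" ")
            if len(parts) != H + 1:
                continue
            tok = parts[0]
            if tok in self.vocab:
                table[self.vocab[tok]] = np.array([float(v) for v in parts[1:]])

    # -- forward passes ----------------------------------------------------

    def _lstm_direction(self, x: ad.Tensor, mask: np.ndarray, l: int,
                        d: str) -> ad.Tensor:
        B, T = mask.shape
        Hd = self.config.hidden_size // 2
        Wx, Wh, b = (self.params[f"Wx{l}{d}"], self.params[f"Wh{l}{d}"],
                     self.params[f"b{l}{d}"])
        h = ad.constant(np.zeros((B, Hd)))
        c = ad.constant(np.zeros((B, Hd)))
        outs = []
        for t in range(T):
            m = mask[:, t][:, None]  # (B, 1): freeze state on padding
            xt = ad.index_axis1(x, t)
            z = xt @ Wx + h @ Wh + b
            i = ad.sigmoid(ad.slice_last(z, 0, Hd))
            f = ad.sigmoid(ad.slice_last(z, Hd, 2 * Hd))
            g = ad.tanh(ad.slice_last(z, 2 * Hd, 3 * Hd))
            o = ad.sigmoid(ad.slice_last(z, 3 * Hd, 4 * Hd))
            c = (f * c + i * g) * m + c * (1.0 - m)
            h = (o * ad.tanh(c)) * m + h * (1.0 - m)
            outs.append(h)
        return ad.stack_axis1(outs)

    def _encode_recurrent(self, ids: np.ndarray, mask: np.ndarray) -> ad.Tensor:
        x = ad.embedding(self.params["embed"], ids)
        for l in range(self.config.layers):
            fwd = self._lstm_direction(x, mask, l, "f")
            bwd = ad.flip_axis1(
                self._lstm_direction(ad.flip_axis1(x), mask[:, ::-1], l, "b"))
            x = ad.concat_last([fwd, bwd])
        return x

    def _encode_attention(self, ids: np.ndarray, mask: np.ndarray) -> ad.Tensor:
        B, T = ids.shape
        H, nh = self.config.hidden_size, self.config.n_heads
        dh = H // nh
        x = ad.embedding(self.params["embed"], ids) + _sinusoidal_positions(T, H)
        key_mask = (1.0 - mask)[:, None, None, :] * -1e9  # pad keys excluded
        for l in range(self.config.layers):
            def heads(w):
                proj = x @ self.params[f"{w}{l}"]
                return ad.transpose(ad.reshape(proj, (B, T, nh, dh)), (0, 2, 1, 3))
            Q, K, V = heads("Wq"), heads("Wk"), heads("Wv")
            scores = (Q @ ad.transpose(K, (0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
            attn = ad.softmax_last(scores + key_mask)
            ctx = ad.reshape(ad.transpose(attn @ V, (0, 2, 1, 3)), (B, T, H))
            x = ad.layer_norm(x + ctx @ self.params[f"Wo{l}"],
                              self.params[f"ln1g{l}"], self.params[f"ln1b{l}"])
            ff = ad.relu(x @ self.params[f"W1_{l}"] + self.params[f"b1_{l}"]) \
                @ self.params[f"W2_{l}"] + self.params[f"b2_{l}"]
            x = ad.layer_norm(x + ff,
                              self.params[f"ln2g{l}"], self.params[f"ln2b{l}"])
        return x

    def _forward(self, ids: np.ndarray, mask: np.ndarray,
                 pool: np.ndarray) -> tuple[ad.Tensor, ad.Tensor]:
        """Return (logits (B,3), anchor embedding (B,H))."""
        if self.config.model_kind == "recurrent":
            enc = self._encode_recurrent(ids, mask)
        else:
            enc = self._encode_attention(ids, mask)
        B = ids.shape[0]
        anchor = ad.reshape(ad.constant(pool) @ enc,
                            (B, self.config.hidden_size))
        logits = anchor @ self.params["Wout"] + self.params["bout"]
        return logits, anchor

    # -- training ----------------------------------------------------------

    def train_on(self, sentences: Sequence[Sentence], labels: Sequence,
                 max_epochs: int | None = None,
                 learning_rate: float | None = None,
                 shuffle_seed: int | None = None) -> None:
        """In-place optimization (used by both train and fine_tune)."""
        cfg = self.config
        epochs = cfg.max_epochs if max_epochs is None else max_epochs
        lr = cfg.learning_rate if learning_rate is None else learning_rate
        y = np.array([CLASS_INDEX[lab] for lab in labels])
        # inverse-frequency class weights: the label mixture is heavily skewed
        counts = np.bincount(y, minlength=3).astype(float)
        weights = np.where(counts > 0, len(y) / (3.0 * np.maximum(counts, 1)), 0.0)
        opt = ad.Adam(self.params.values(), lr=lr)
        rng = np.random.default_rng(cfg.seed if shuffle_seed is None
                                    else shuffle_seed)
        n = len(sentences)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                ids, mask, pool = encode_batch(
                    [sentences[i] for i in batch], self.vocab, cfg.max_len)
                logits, _ = self._forward(ids, mask, pool)
                loss = ad.cross_entropy_logits(logits, y[batch],
                                               weights[y[batch]])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss ({loss.data}) for kind "
                        f"{cfg.model_kind}; lower the learning rate")
                opt.zero_grad()
                loss.backward()
                opt.step()

    @classmethod
    def fit(cls, config: ModelConfig, sentences: Sequence[Sentence],
            labels: Sequence) -> "NeuralModel":
        y = {CLASS_INDEX[lab] for lab in labels}
        if len(y) < 2:
            raise ValueError("training data contains a single class; "
                             "need examples of at least 2 classes")
        vocab = build_vocab([s.text for s in sentences])
        model = cls.init(config, vocab)
        model.train_on(sentences, labels)
        return model

    def fine_tune(self, sentences: Sequence[Sentence], labels: Sequence,
                  max_epochs: int | None = None) -> "NeuralModel":
        """Continue optimization from current weights at reduced rate.

        Returns a new model; ``self`` is left unchanged.  Zero epochs is
        the identity (a plain copy).
        """
        if not sentences:
            raise ValueError("fine_tune requires at least one labeled sentence")
        new = NeuralModel(self.config, dict(self.vocab),
                          {k: ad.parameter(v.data.copy())
                           for k, v in self.params.items()})
        epochs = self.config.max_epochs if max_epochs is None else max_epochs
        if epochs > 0:
            new.train_on(
                sentences, labels, max_epochs=epochs,
                learning_rate=self.config.learning_rate
                * self.config.finetune_lr_factor,
                shuffle_seed=self.config.seed + 7)
        return new

    # -- inference ---------------------------------------------------------

    def predict(self, sentences: Sequence[Sentence]) -> list[PredictionScore]:
        out: list[PredictionScore] = []
        bs = self.config.batch_size
        for start in range(0, len(sentences), bs):
            chunk = sentences[start:start + bs]
            ids, mask, pool = encode_batch(chunk, self.vocab, self.config.max_len)
            logits, anchor = self._forward(ids, mask, pool)
            z = logits.data - logits.data.max(axis=-1, keepdims=True)
            e = np.exp(z)
            scores = e / e.sum(axis=-1, keepdims=True)
            for i in range(len(chunk)):
                out.append(score_from_vector(scores[i], anchor.data[i]))
        return out

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(
            {**self.config.__dict__, "kind": self.config.model_kind},
            default=list))
        (directory / "vocab.json").write_text(json.dumps(self.vocab))
        np.savez(directory / "weights.npz",
                 **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, directory: str | Path, config: ModelConfig) -> "NeuralModel":
        directory = Path(directory)
        vocab = json.loads((directory / "vocab.json").read_text())
        arrays = np.load(directory / "weights.npz")
        params = {k: ad.parameter(arrays[k]) for k in arrays.files}
        return cls(config, vocab, params)
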