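"""Iterative labeling loop: patterns -> train -> score -> map -> query.

Implements the label-acquisition procedure used to build the gold
standard: round 0 seeds with a uniform random sample; every later round
propagates the always patterns, trains a classifier on everything
labeled so far, scores the unlabeled pool, projects sentence embeddings
to a 2-D map, and queries the next candidate batch half by prediction
entropy (uncertainty) and half by greedy farthest-point coverage of the
map (diversity).  A simulated oracle closes the loop in tests; in
production the query files are labeling queues for human experts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import classifiers
from .classifiers import ModelConfig, PredictionScore
from .corpus import Sentence
from .labels import Label, Provenance
from .patterns import AlwaysPattern, LabeledSentence, coverage, propagate
from .evaluation import f1_scores

__all__ = [
    "EmbeddingMap", "QueryBatch", "LoopResult",
    "entropy_uncertainty", "build_embedding_map", "diversity_select",
    "build_query", "run_loop",
]


def entropy_uncertainty(score: "PredictionScore | np.ndarray") -> float:
    """Shannon entropy (nats) of a prediction-score triple.

    Maximal (ln 3) at the uniform distribution; 0 for a one-hot score;
    ``0 * ln 0 := 0``.  Negative score entries raise.
    """
    p = score.scores if isinstance(score, PredictionScore) else np.asarray(score, float)
    if (p < 0).any():
        raise ValueError("scores must be nonnegative")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass(frozen=True)
class EmbeddingMap:
    """2-D coordinates of sentence embedding vectors."""

    points: np.ndarray  # (n, 2)
    source: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.isfinite(pts).all():
            raise ValueError("map coordinates must be finite")
        object.__setattr__(self, "points", pts)


def build_embedding_map(vectors: np.ndarray, method: str = "umap",
                        seed: int = 0) -> EmbeddingMap:
    """Project embedding vectors to 2-D.

    ``method="umap"`` is the neighborhood-preserving default;
    ``method="pca"`` is a fast, fully deterministic alternative used in
    tests and small loops.  Both run behind the same interface.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be (n, d)")
    n = vectors.shape[0]
    if method == "pca" or n < 5:
        centered = vectors - vectors.mean(axis=0)
        # top-2 principal axes via SVD, sign-fixed for determinism
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        k = min(2, vt.shape[0])
        axes = vt[:k].copy()
        for row in axes:
            if row[np.abs(row).argmax()] < 0:
                row *= -1.0
        pts = centered @ axes.T
        if k < 2:
            pts = np.column_stack([pts, np.zeros(n)])
        return EmbeddingMap(points=pts, source="pca")
    if method == "umap":
        import umap  # heavy import; deferred

        reducer = umap.UMAP(n_components=2, random_state=seed)
        return EmbeddingMap(points=reducer.fit_transform(vectors), source="umap")
    raise ValueError(f"unknown embedding-map method {method!r}")


def diversity_select(emap: EmbeddingMap, already_chosen: Iterable[int],
                     k: int) -> list[int]:
    """Greedy farthest-point (k-center) selection on the map.

    The first pick is the eligible point farthest from the centroid of
    the already-chosen (labeled) points — or of all points when nothing
    is labeled yet; each later pick maximizes its minimum distance to
    everything chosen so far.  Ties break toward the lowest index, so
    the selection is deterministic given input order.
    """
    pts = emap.points
    chosen = sorted(set(already_chosen))
    eligible = np.array([i for i in range(len(pts)) if i not in set(chosen)])
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds {len(eligible)} eligible points")
    if k == 0:
        return []
    centroid = pts[chosen].mean(axis=0) if chosen else pts.mean(axis=0)
    d_centroid = np.linalg.norm(pts[eligible] - centroid, axis=1)
    picks = [int(eligible[int(np.argmax(d_centroid))])]
    if chosen:
        mind = np.min(np.linalg.norm(
            pts[eligible][:, None, :] - pts[chosen][None, :, :], axis=2), axis=1)
    else:
        mind = np.full(len(eligible), np.inf)
    mind = np.minimum(mind, np.linalg.norm(pts[eligible] - pts[picks[0]], axis=1))
    taken = {picks[0]}
    while len(picks) < k:
        best = -1
        best_d = -np.inf
        for j, i in enumerate(eligible):
            if i in taken:
                continue
            if mind[j] > best_d:
                best_d = mind[j]
                best = j
        picks.append(int(eligible[best]))
        taken.add(int(eligible[best]))
        mind = np.minimum(mind, np.linalg.norm(
            pts[eligible] - pts[picks[-1]], axis=1))
    return picks


@dataclass(frozen=True)
class QueryBatch:
    """The next labeling queue: sentence indices plus strategy tags."""

    round: int
    candidates: tuple[int, ...]
    strategy_tags: tuple[str, ...]

    def __post_init__(self):
        if len(self.candidates) != len(set(self.candidates)):
            raise ValueError("query batch contains duplicates")
        if len(self.candidates) != len(self.strategy_tags):
            raise ValueError("one strategy tag per candidate required")

    def __len__(self) -> int:
        return len(self.candidates)


def build_query(
    scores: Sequence[PredictionScore] | None,
    emap: EmbeddingMap | None,
    batch_size: int,
    round: int,
    labeled: Iterable[int] = (),
    seed: int = 0,
) -> QueryBatch:
    """Select the next candidate batch from the unlabeled pool.

    Round 0 draws a seeded uniform random sample (no model yet).  Later
    rounds take the ceil(k/2) highest-entropy sentences plus floor(k/2)
    diversity picks from the map, excluding everything labeled and the
    uncertainty picks; shortfalls backfill by next-highest entropy.  An
    empty unlabeled pool yields an empty batch (loop termination).
    """
    labeled_set = set(labeled)
    if round == 0:
        if emap is not None:
            n = len(emap.points)
        elif scores is not None:
            n = len(scores)
        else:
            raise ValueError("round 0 needs scores or a map to size the pool")
        pool = np.array([i for i in range(n) if i not in labeled_set])
        if len(pool) == 0:
            return QueryBatch(round=0, candidates=(), strategy_tags=())
        rng = np.random.default_rng(seed)
        take = min(batch_size, len(pool))
        picks = rng.choice(pool, size=take, replace=False)
        return QueryBatch(round=0, candidates=tuple(int(i) for i in picks),
                          strategy_tags=("seed_random",) * take)
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 for rounds >= 1")
    if scores is None or emap is None:
        raise ValueError("rounds >= 1 need prediction scores and a map")
    n = len(scores)
    unlabeled = [i for i in range(n) if i not in labeled_set]
    if not unlabeled:
        return QueryBatch(round=round, candidates=(), strategy_tags=())
    k = min(batch_size, len(unlabeled))
    n_unc = math.ceil(k / 2)
    n_div = k - n_unc
    ent = {i: entropy_uncertainty(scores[i]) for i in unlabeled}
    by_entropy = sorted(unlabeled, key=lambda i: (-ent[i], i))
    unc_picks = by_entropy[:n_unc]
    div_picks: list[int] = []
    if n_div > 0:
        div_picks = diversity_select(
            emap, already_chosen=labeled_set | set(unc_picks), k=n_div)
    candidates = list(unc_picks) + list(div_picks)
    tags = ["uncertainty"] * len(unc_picks) + ["diversity"] * len(div_picks)
    # backfill any shortfall (defensive; dedup is structural) by next entropy
    backfill = (i for i in by_entropy if i not in set(candidates))
    while len(candidates) < k:
        candidates.append(next(backfill))
        tags.append("uncertainty")
    return QueryBatch(round=round, candidates=tuple(candidates),
                      strategy_tags=tuple(tags))


# ---------------------------------------------------------------------------
# the loop

@dataclass
class LoopResult:
    history: pd.DataFrame
    labeled: dict[tuple[str, int], LabeledSentence]
    model: object | None = None
    aborted: bool = False
    error: str | None = None


def run_loop(
    sentences: Sequence[Sentence],
    patterns: Sequence[AlwaysPattern],
    oracle: Callable[[Sentence], Label],
    rounds: int = 5,
    batch_size: int = 200,
    config: ModelConfig | None = None,
    seed: int = 0,
    map_method: str = "pca",
    strategy: str = "active",
    holdout: Sequence[Sentence] = (),
    holdout_labels: Sequence[Label] = (),
) -> LoopResult:
    """Run the iterative labeling loop with a labeling callback.

    Executes the seed round plus ``rounds`` active rounds.  Each active
    round: propagate patterns over the unlabeled pool, train the
    configured model on all labels, score the remaining pool, build the
    embedding map, query the next batch, and hand it to ``oracle``.
    ``strategy="random"`` replaces the uncertainty+diversity query with
    a uniform random one (ablation baseline).  History rows carry
    cumulative label counts by provenance, pattern coverage, and
    held-out micro/macro F1 when a holdout set is supplied.

    An oracle exception aborts the loop and returns the partial history
    with ``aborted=True``.
    """
    if strategy not in ("active", "random"):
        raise ValueError("strategy must be 'active' or 'random'")
    if config is None:
        # the recurrent model is the loop default; small for CPU rounds
        config = ModelConfig(model_kind="recurrent", hidden_size=32,
                             max_epochs=4, seed=seed)
    sentences = list(sentences)
    labeled: dict[tuple[str, int], LabeledSentence] = {}
    rows: list[dict] = []
    model = None

    def label_batch(batch: QueryBatch, round_no: int) -> str | None:
        for i in batch.candidates:
            sent = sentences[i]
            try:
                lab = oracle(sent)
            except Exception as exc:  # noqa: BLE001 — abort contract
                return f"oracle failed on {sent.key}: {exc}"
            labeled[sent.key] = LabeledSentence(
                sentence=sent, label=lab, provenance=Provenance.HUMAN,
                round=round_no)
        return None

    def record(round_no: int) -> None:
        prov = [ls.provenance for ls in labeled.values()]
        cov, _ = coverage(patterns, sentences) if patterns and sentences \
            else (0.0, 0)
        row = {
            "round": round_no,
            "n_human": sum(p is Provenance.HUMAN for p in prov),
            "n_pattern": sum(p is Provenance.PATTERN for p in prov),
            "n_labeled": len(labeled),
            "coverage": cov,
            "holdout_micro_f1": np.nan,
            "holdout_macro_f1": np.nan,
        }
        if model is not None and len(holdout) > 0:
            preds = classifiers.predict(model, holdout)
            rep = f1_scores(list(holdout_labels),
                            [p.predicted_label for p in preds])
            row["holdout_micro_f1"] = rep.micro_f1
            row["holdout_macro_f1"] = rep.macro_f1
        rows.append(row)

    def result(aborted: bool = False, error: str | None = None) -> LoopResult:
        return LoopResult(history=pd.DataFrame(rows), labeled=labeled,
                          model=model, aborted=aborted, error=error)

    # round 0: seeded random sample
    batch = build_query(None, EmbeddingMap(np.zeros((len(sentences), 2))),
                        batch_size, 0, labeled=(), seed=seed)
    err = label_batch(batch, 0)
    if err:
        record(0)
        return result(aborted=True, error=err)
    record(0)

    index_of = {s.key: i for i, s in enumerate(sentences)}
    for r in range(1, rounds + 1):
        # step 2: pattern propagation over the unlabeled pool
        pool = [s for s in sentences if s.key not in labeled]
        if patterns:
            pattern_labeled, _ = propagate(patterns, pool, round=r)
            for ls in pattern_labeled:
                labeled[ls.key] = ls
        # steps 3-4: train on all labels, score the remaining pool
        pool = [s for s in sentences if s.key not in labeled]
        try:
            model = classifiers.train(config, list(labeled.values()))
        except ValueError:
            model = None  # single-class label set so far; keep querying
        if not pool:
            record(r)
            break
        if strategy == "random" or model is None:
            rng_batch = build_query(
                None, EmbeddingMap(np.zeros((len(sentences), 2))),
                batch_size, 0, labeled=[index_of[k] for k in labeled],
                seed=seed + 1000 * r)
            batch = QueryBatch(round=r, candidates=rng_batch.candidates,
                               strategy_tags=rng_batch.strategy_tags)
        else:
            # steps 4-6: scores, embedding map, dual-strategy query
            scores_pool = classifiers.predict(model, pool)
            vectors = np.stack([p.embedding for p in scores_pool])
            emap_pool = build_embedding_map(vectors, method=map_method,
                                            seed=seed + r)
            pool_idx = [index_of[s.key] for s in pool]
            # queries operate on the pool; translate back to corpus indices
            sub = build_query(scores_pool, emap_pool, batch_size, r,
                              labeled=(), seed=seed + r)
            batch = QueryBatch(
                round=r,
                candidates=tuple(pool_idx[i] for i in sub.candidates),
                strategy_tags=sub.strategy_tags)
        err = label_batch(batch, r)
        if err:
            record(r)
            return result(aborted=True, error=err)
        record(r)
    return result()
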