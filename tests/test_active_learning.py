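"""Uncertainty entropy, diversity selection, query building, and the loop."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delirium_nlp import classifiers, corpus, synthetic
from delirium_nlp.active_learning import (EmbeddingMap, QueryBatch,
                                          build_embedding_map, build_query,
                                          diversity_select, entropy_uncertainty,
                                          run_loop)
from delirium_nlp.classifiers.config import score_from_vector
from delirium_nlp.labels import Label


def make_scores(p):
    return score_from_vector(np.asarray(p, float), np.zeros(2))


class TestEntropy:
    def test_uniform_is_maximal_ln3(self):
        assert entropy_uncertainty(make_scores([1 / 3] * 3)) == \
            pytest.approx(np.log(3))

    def test_one_hot_is_zero(self):
        assert entropy_uncertainty(make_scores([1, 0, 0])) == 0.0

    def test_half_quarter_quarter(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397...
        assert entropy_uncertainty(make_scores([0.5, 0.25, 0.25])) == \
            pytest.approx(1.0397, abs=1e-4)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            entropy_uncertainty(np.array([-0.1, 0.6, 0.5]))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    def test_bounds_and_permutation_invariance(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = entropy_uncertainty(p)
        assert -1e-12 <= h <= np.log(3) + 1e-12
        assert entropy_uncertainty(p[::-1].copy()) == pytest.approx(h)


def brute_force_greedy(points, already, k):
    """From-scratch greedy max-min reference (recomputes everything)."""
    chosen = sorted(set(already))
    eligible = [i for i in range(len(points)) if i not in set(chosen)]
    centroid = points[chosen].mean(axis=0) if chosen else points.mean(axis=0)
    picks = []
    for step in range(k):
        best, best_d = None, -np.inf
        for i in eligible:
            if i in picks:
                continue
            if step == 0 and not picks:
                d = np.linalg.norm(points[i] - centroid)
            else:
                ref = chosen + picks
                d = min(np.linalg.norm(points[i] - points[j]) for j in ref)
            if d > best_d:
                best, best_d = i, d
        picks.append(best)
    return picks


class TestDiversity:
    def test_two_clusters_one_pick_each(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (10, 2))
        b = rng.normal(10, 0.1, (10, 2))
        emap = EmbeddingMap(np.vstack([a, b]))
        picks = diversity_select(emap, already_chosen=(), k=2)
        assert {p < 10 for p in picks} == {True, False}
        # brute-force max-min over all pairs agrees on the cluster split
        pts = emap.points
        best_pair = max(((i, j) for i in range(20) for j in range(i + 1, 20)),
                        key=lambda ij: np.linalg.norm(pts[ij[0]] - pts[ij[1]]))
        assert {p < 10 for p in best_pair} == {True, False}

    def test_k_equals_all_eligible_returns_all(self):
        emap = EmbeddingMap(np.random.default_rng(1).normal(size=(8, 2)))
        picks = diversity_select(emap, already_chosen=(0, 1), k=6)
        assert sorted(picks) == [2, 3, 4, 5, 6, 7]

    def test_k_one_is_farthest_from_labeled_centroid(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2))
        labeled = [0, 5, 9]
        emap = EmbeddingMap(pts)
        (pick,) = diversity_select(emap, already_chosen=labeled, k=1)
        centroid = pts[labeled].mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        dists[labeled] = -np.inf  # exhaustive scan over eligible points
        assert pick == int(np.argmax(dists))

    def test_k_beyond_eligible_rejected(self):
        emap = EmbeddingMap(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="eligible"):
            diversity_select(emap, already_chosen=(0,), k=3)

    def test_matches_brute_force_greedy_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 100))
            pts = rng.normal(size=(n, 2))
            labeled = list(rng.choice(n, size=int(rng.integers(0, n // 3 + 1)),
                                      replace=False))
            k = int(rng.integers(1, n - len(labeled) + 1))
            emap = EmbeddingMap(pts)
            assert diversity_select(emap, labeled, k) == \
                brute_force_greedy(pts, labeled, k)


class TestBuildQuery:
    @staticmethod
    def pool(n, seed=0):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(3), size=n)
        scores = [make_scores(r) for r in raw]
        emap = EmbeddingMap(rng.normal(size=(n, 2)))
        return scores, emap

    def test_half_uncertainty_half_diversity(self):
        scores, emap = self.pool(60)
        batch = build_query(scores, emap, batch_size=10, round=1)
        assert len(batch) == 10
        assert batch.strategy_tags.count("uncertainty") == 5
        assert batch.strategy_tags.count("diversity") == 5

    def test_odd_batch_favors_uncertainty_by_one(self):
        scores, emap = self.pool(60)
        batch = build_query(scores, emap, batch_size=9, round=1)
        assert batch.strategy_tags.count("uncertainty") == 5
        assert batch.strategy_tags.count("diversity") == 4

    def test_everything_labeled_yields_empty_batch(self):
        scores, emap = self.pool(10)
        batch = build_query(scores, emap, 4, round=2, labeled=range(10))
        assert len(batch) == 0

    def test_dominant_entropy_point_always_selected(self):
        rng = np.random.default_rng(4)
        raw = np.tile([0.98, 0.01, 0.01], (40, 1))
        raw[17] = [1 / 3, 1 / 3, 1 / 3]
        scores = [make_scores(r) for r in raw]
        emap = EmbeddingMap(rng.normal(size=(40, 2)))
        for bs in (2, 6, 12):
            batch = build_query(scores, emap, bs, round=1)
            assert 17 in batch.candidates

    def test_round0_is_seeded_uniform_sample(self):
        _, emap = self.pool(30)
        a = build_query(None, emap, 8, round=0, seed=5)
        b = build_query(None, emap, 8, round=0, seed=5)
        assert a.candidates == b.candidates
        assert set(a.strategy_tags) == {"seed_random"}

    def test_batch_never_contains_labeled(self):
        scores, emap = self.pool(30)
        labeled = set(range(0, 30, 2))
        batch = build_query(scores, emap, 10, round=1, labeled=labeled)
        assert not set(batch.candidates) & labeled

    def test_duplicates_rejected_by_contract(self):
        with pytest.raises(ValueError, match="duplicates"):
            QueryBatch(round=1, candidates=(1, 1), strategy_tags=("a", "b"))


class TestEmbeddingMaps:
    def test_pca_map_is_deterministic_and_finite(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 16))
        a = build_embedding_map(X, method="pca")
        b = build_embedding_map(X, method="pca")
        assert np.array_equal(a.points, b.points)
        assert a.points.shape == (40, 2)

    def test_umap_map_smoke(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (30, 8)), rng.normal(6, 1, (30, 8))])
        emap = build_embedding_map(X, method="umap", seed=0)
        assert emap.points.shape == (60, 2)
        assert np.isfinite(emap.points).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            build_embedding_map(np.zeros((10, 3)), method="tsne")


@pytest.fixture(scope="module")
def loop_setup():
    cohort = synthetic.generate(synthetic.GeneratorConfig(n_patients=120,
                                                          seed=31))
    sentences = corpus.extract_keyword_sentences(cohort.notes)
    oracle = synthetic.oracle_from_truth(cohort)
    config = classifiers.ModelConfig(model_kind="linear_ngram", seed=0)
    return cohort, sentences, oracle, config


class TestLoop:
    def test_labeled_count_monotone_and_coverage_non_decreasing(self, loop_setup):
        _, sentences, oracle, config = loop_setup
        res = run_loop(sentences, synthetic.default_always_patterns(), oracle,
                       rounds=3, batch_size=15, config=config, seed=0)
        assert not res.aborted
        n = res.history["n_labeled"].to_numpy()
        cov = res.history["coverage"].to_numpy()
        assert (np.diff(n) >= 0).all()
        assert (np.diff(cov) >= -1e-12).all()

    def test_zero_rounds_history_is_seed_batch_only(self, loop_setup):
        _, sentences, oracle, config = loop_setup
        res = run_loop(sentences, [], oracle, rounds=0, batch_size=10,
                       config=config, seed=1)
        assert list(res.history["round"]) == [0]
        assert res.history["n_human"].iloc[0] == 10

    def test_oracle_failure_aborts_with_partial_history(self, loop_setup):
        _, sentences, _, config = loop_setup
        calls = {"n": 0}

        def flaky(sentence):
            calls["n"] += 1
            if calls["n"] > 12:
                raise RuntimeError("annotator went home")
            return Label.NEITHER if calls["n"] % 3 else Label.POSITIVE

        res = run_loop(sentences, [], flaky, rounds=3, batch_size=10,
                       config=config, seed=2)
        assert res.aborted
        assert "annotator went home" in res.error
        assert len(res.history) >= 1

    def test_loop_reproducible_given_seed(self, loop_setup):
        _, sentences, oracle, config = loop_setup
        a = run_loop(sentences, [], oracle, rounds=2, batch_size=10,
                     config=config, seed=3)
        b = run_loop(sentences, [], oracle, rounds=2, batch_size=10,
                     config=config, seed=3)
        assert a.history.equals(b.history)
        assert set(a.labeled) == set(b.labeled)

    def test_final_coverage_at_least_first_round(self, loop_setup):
        _, sentences, oracle, config = loop_setup
        res = run_loop(sentences, synthetic.default_always_patterns(), oracle,
                       rounds=5, batch_size=10, config=config, seed=4)
        cov = res.history["coverage"].to_numpy()
        assert cov[-1] >= cov[0]
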