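"""DDAG elimination, root selection, and the five probability-fusion rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesiondag import (
    AGGREGATION_METHODS,
    DDAGStructure,
    PairwiseScoreSet,
    aggregate,
    ddag_predict,
    ddag_predict_batch,
    pairwise_from_multiclass,
    select_root,
)
from .conftest import condorcet_score_set, ddag_oracle, random_score_set


class TestDDAGPredict:
    def test_condorcet_winner_for_every_root(self, rng):
        scores, winner = condorcet_score_set(rng, 3)
        for order in itertools.permutations(range(3)):
            rec = ddag_predict(scores, DDAGStructure(order))
            assert rec.predicted_class == winner

    def test_cyclic_scores_depend_on_root(self):
        # 0 beats 1, 1 beats 2, 2 beats 0, each 0.6/0.4
        scores = PairwiseScoreSet(
            scores={(0, 1): (0.6, 0.4), (1, 2): (0.6, 0.4), (0, 2): (0.4, 0.6)}
        )
        assert ddag_predict(scores, DDAGStructure((1, 2, 0))).predicted_class == 0
        assert ddag_predict(scores, DDAGStructure((0, 1, 2))).predicted_class == 2
        assert ddag_predict(scores, DDAGStructure((2, 0, 1))).predicted_class == 1

    def test_two_classes_single_comparison(self):
        scores = PairwiseScoreSet(scores={(0, 1): (0.3, 0.7)})
        rec = ddag_predict(scores, DDAGStructure((0, 1)))
        assert rec.predicted_class == 1
        assert rec.n_nodes == 1
        assert rec.path == [((0, 1), 0)]

    @pytest.mark.parametrize("K", range(2, 9))
    def test_path_length_is_k_minus_one(self, K, rng):
        scores = random_score_set(rng, K)
        rec = ddag_predict(scores, DDAGStructure(tuple(range(K))))
        eliminated = [e for _, e in rec.path]
        assert rec.n_nodes == K - 1
        assert len(set(eliminated)) == K - 1
        assert rec.predicted_class not in eliminated

    def test_tie_eliminates_larger_index(self):
        scores = PairwiseScoreSet(
            scores={(0, 1): (0.5, 0.5), (0, 2): (0.9, 0.1), (1, 2): (0.9, 0.1)}
        )
        rec = ddag_predict(scores, DDAGStructure((0, 1, 2)))
        assert rec.path[0] == ((0, 1), 1)

    def test_missing_pair_rejected(self, rng):
        scores = PairwiseScoreSet(scores={(0, 1): (0.6, 0.4)})
        with pytest.raises(ValueError):
            ddag_predict(scores, DDAGStructure((0, 1, 2)))

    def test_agrees_with_sequential_champion_oracle(self, rng):
        """500 random score sets, random orders, K in 3..5."""
        for _ in range(500):
            K = int(rng.integers(3, 6))
            scores = random_score_set(rng, K)
            order = tuple(rng.permutation(K))
            assert (
                ddag_predict(scores, DDAGStructure(order)).predicted_class
                == ddag_oracle(scores, order)
            )


class TestDDAGBatch:
    def test_empty_batch(self):
        labels, records = ddag_predict_batch([], DDAGStructure((0, 1)))
        assert len(labels) == 0 and records == []

    def test_singleton_matches_scalar(self, rng):
        scores = random_score_set(rng, 4)
        structure = DDAGStructure((2, 0, 3, 1))
        labels, records = ddag_predict_batch([scores], structure)
        assert labels[0] == ddag_predict(scores, structure).predicted_class

    def test_batch_order_preserved(self, rng):
        sets = [random_score_set(rng, 3) for _ in range(50)]
        structure = DDAGStructure((0, 1, 2))
        labels, _ = ddag_predict_batch(sets, structure)
        expected = [ddag_predict(s, structure).predicted_class for s in sets]
        assert np.array_equal(labels, expected)


class TestSelectRoot:
    def test_best_validation_pair_wins(self):
        structure = select_root({(0, 1): 0.806, (0, 2): 0.858, (1, 2): 0.867})
        assert structure.root_pair == (1, 2)
        assert structure.class_order == (1, 2, 0)

    def test_tie_breaks_lexicographically(self):
        structure = select_root({(0, 1): 0.8, (0, 2): 0.8, (1, 2): 0.8})
        assert structure.root_pair == (0, 1)

    def test_insertion_order_irrelevant(self, rng):
        items = [((0, 1), 0.7), ((0, 2), 0.9), ((1, 2), 0.8)]
        results = set()
        for perm in itertools.permutations(items):
            results.add(select_root(dict(perm)).class_order)
        assert results == {(0, 2, 1)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_root({})


class TestAggregate:
    def test_avg_hand_example(self):
        stack = np.array([[[0.2, 0.5, 0.3]], [[0.4, 0.4, 0.2]]])
        np.testing.assert_allclose(aggregate(stack, "avg"), [[0.3, 0.45, 0.25]], atol=1e-9)

    def test_max_win_hand_example_unique_maxima(self):
        # argmaxes are class 1 and class 0 -> one vote each
        stack = np.array([[[0.2, 0.5, 0.3]], [[0.45, 0.35, 0.2]]])
        np.testing.assert_allclose(aggregate(stack, "max_win"), [[0.5, 0.5, 0.0]], atol=1e-9)

    def test_max_win_tie_splits_vote(self):
        stack = np.array([[[0.4, 0.4, 0.2]]])
        np.testing.assert_allclose(aggregate(stack, "max_win"), [[0.5, 0.5, 0.0]], atol=1e-9)

    def test_identical_classifiers_idempotent(self, rng):
        probs = rng.dirichlet(np.ones(4), size=20)
        stack = np.stack([probs] * 3)
        for method in ("avg", "gmean", "mconf", "max_win"):
            np.testing.assert_allclose(aggregate(stack, method), aggregate(stack[:1], method),
                                       atol=1e-9)
        np.testing.assert_allclose(aggregate(stack, "avg"), probs, atol=1e-9)
        np.testing.assert_allclose(aggregate(stack, "gmean"), probs, atol=1e-9)
        # prod returns the renormalized m-th power
        cubed = probs**3
        np.testing.assert_allclose(
            aggregate(stack, "prod"), cubed / cubed.sum(axis=1, keepdims=True), atol=1e-9
        )

    def test_single_classifier_identity(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        for method in ("avg", "prod", "gmean", "mconf"):
            np.testing.assert_allclose(aggregate(probs[None], method), probs, atol=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        m=st.integers(1, 5),
        K=st.integers(2, 6),
        n=st.integers(1, 8),
        seed=st.integers(0, 1000),
        method=st.sampled_from(AGGREGATION_METHODS),
    )
    def test_output_rows_are_probability_vectors(self, m, K, n, seed, method):
        stack = np.random.default_rng(seed).dirichlet(np.ones(K), size=(m, n))
        out = aggregate(stack, method)
        assert out.shape == (n, K)
        assert (out >= 0).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_prod_is_classifier_order_invariant(self, rng):
        stack = rng.dirichlet(np.ones(3), size=(4, 15))
        base = aggregate(stack, "prod")
        for perm in itertools.permutations(range(4)):
            np.testing.assert_allclose(aggregate(stack[list(perm)], "prod"), base, atol=1e-12)

    def test_bad_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate(np.empty((0, 3, 2)), "avg")
        with pytest.raises(ValueError):
            aggregate(rng.dirichlet(np.ones(3), size=(2, 5)), "median")


class TestPairwiseFromMulticlass:
    def test_hand_example(self):
        scores = pairwise_from_multiclass(np.array([0.6, 0.3, 0.1]))
        pi, pj = scores.scores[(0, 1)]
        assert pi == pytest.approx(2 / 3)
        assert pj == pytest.approx(1 / 3)

    def test_uniform_row_all_ties(self):
        scores = pairwise_from_multiclass(np.full(4, 0.25))
        assert all(v == (0.5, 0.5) for v in scores.scores.values())

    def test_one_hot_row_dominates(self):
        with pytest.warns(UserWarning):  # the off-classes' mutual pair is degenerate
            scores = pairwise_from_multiclass(np.array([0.0, 1.0, 0.0]))
        assert scores.confidence(1, 0) == 1.0
        assert scores.confidence(1, 2) == 1.0

    def test_zero_pair_sum_warns_and_ties(self):
        with pytest.warns(UserWarning):
            scores = pairwise_from_multiclass(np.array([1.0, 0.0, 0.0]))
        assert scores.scores[(1, 2)] == (0.5, 0.5)


class TestScoreSetValidation:
    def test_unnormalized_pair_rejected(self):
        with pytest.raises(ValueError):
            PairwiseScoreSet(scores={(0, 1): (0.7, 0.7)})

    def test_unordered_pair_rejected(self):
        with pytest.raises(ValueError):
            PairwiseScoreSet(scores={(1, 0): (0.5, 0.5)})
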