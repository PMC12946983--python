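"""Pairwise joint entropies, the batch-entropy approximation, and optimizers."""

import itertools

import numpy as np
import pytest

from lipal import acquisition
from lipal.acquisition import (
    Batch,
    EntropyMatrix,
    approx_joint_entropy,
    build_entropy_matrix,
    pairwise_entropy,
    select_batch,
)
from lipal.model import PosteriorSamples

from conftest import random_posterior


def brute_force_joint_entropy(probs: np.ndarray) -> float:
    """True joint entropy in bits of the mixture of product Bernoullis."""
    n, T = probs.shape
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        p = np.mean(
            np.prod(
                [probs[i] if o else 1 - probs[i] for i, o in enumerate(outcome)], axis=0
            )
        )
        if p > 0:
            total -= p * np.log2(p)
    return total


class TestPairwiseEntropy:
    def test_certain_draws_have_zero_entropy(self):
        table, h = pairwise_entropy(np.ones(10), np.ones(10))
        assert h == 0.0
        assert table[1, 1] == pytest.approx(1.0)

    def test_independent_uniform_is_two_bits(self):
        table, h = pairwise_entropy(np.full(10, 0.5), np.full(10, 0.5))
        np.testing.assert_allclose(table, 0.25)
        assert h == pytest.approx(2.0)

    def test_perfectly_correlated_mixture_is_one_bit(self):
        pi = np.array([1.0, 0.0])
        table, h = pairwise_entropy(pi, pi)
        assert table[0, 0] == pytest.approx(0.5) and table[1, 1] == pytest.approx(0.5)
        assert h == pytest.approx(1.0)

    def test_table_sums_to_one(self):
        rng = np.random.default_rng(0)
        table, _ = pairwise_entropy(rng.random(25), rng.random(25))
        assert table.sum() == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_entropy(np.ones(3), np.ones(4))


class TestBuildEntropyMatrix:
    def test_symmetric_and_matches_scalar_path(self):
        rng = np.random.default_rng(5)
        samples = PosteriorSamples(probs=rng.random((6, 30)))
        m = build_entropy_matrix(samples)
        assert m.H.shape == (6, 6)
        np.testing.assert_allclose(m.H, m.H.T, atol=1e-12)
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            _, h = pairwise_entropy(samples.probs[i], samples.probs[j])
            assert m.H[i, j] == pytest.approx(h, abs=1e-9)

    def test_certain_candidate_row_collapses_to_marginals(self):
        probs = np.vstack([np.ones(20), np.random.default_rng(1).random((4, 20))])
        m = build_entropy_matrix(PosteriorSamples(probs=probs))
        for j in range(1, 5):
            assert m.H[0, j] == pytest.approx(m.H[j, j], abs=1e-9)

    def test_bounds_on_random_posteriors(self):
        """max marginal <= pairwise <= sum of marginals, entries in [0, 2] bits."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = build_entropy_matrix(random_posterior(rng, int(rng.integers(3, 12))))
            d = np.diag(m.H)
            assert m.H.min() >= -1e-9 and m.H.max() <= 2 + 1e-9
            lower = np.maximum(d[:, None], d[None, :])
            upper = d[:, None] + d[None, :]
            off = ~np.eye(m.n, dtype=bool)
            assert (m.H[off] >= lower[off] - 1e-9).all()
            assert (m.H[off] <= upper[off] + 1e-9).all()

    def test_duplicate_candidates_rejected(self):
        samples = PosteriorSamples(probs=np.random.default_rng(0).random((5, 10)))
        with pytest.raises(ValueError):
            build_entropy_matrix(samples, candidates=[0, 1, 1])


class TestApproxJointEntropy:
    def test_exact_at_pair(self):
        rng = np.random.default_rng(2)
        probs = rng.random((2, 50))
        m = build_entropy_matrix(PosteriorSamples(probs=probs))
        approx = approx_joint_entropy(m, Batch(indices=(0, 1)))
        assert approx == pytest.approx(m.H[0, 1], abs=1e-12)
        assert approx == pytest.approx(brute_force_joint_entropy(probs), abs=1e-9)

    def test_exact_for_independent_uniform_triple(self):
        probs = np.full((3, 8), 0.5)
        m = build_entropy_matrix(PosteriorSamples(probs=probs))
        approx = approx_joint_entropy(m, Batch(indices=(0, 1, 2)))
        assert approx == pytest.approx(3.0, abs=1e-9)
        assert approx == pytest.approx(brute_force_joint_entropy(probs), abs=1e-9)

    def test_overestimates_correlated_triple(self):
        probs = np.tile(np.array([1.0, 0.0]), (3, 1))
        m = build_entropy_matrix(PosteriorSamples(probs=probs))
        approx = approx_joint_entropy(m, Batch(indices=(0, 1, 2)))
        true = brute_force_joint_entropy(probs)
        assert approx == pytest.approx(1.5, abs=1e-9)
        assert true == pytest.approx(1.0, abs=1e-9)
        assert approx > true

    def test_pair_minimum_enforced(self):
        m = EntropyMatrix(H=np.eye(3))
        with pytest.raises(ValueError):
            approx_joint_entropy(m, Batch(indices=(0,)))


def _matrix_from_pairs(n, pairs):
    H = np.zeros((n, n))
    for (i, j), v in pairs.items():
        H[i, j] = H[j, i] = v
    return EntropyMatrix(H=H)


FOUR_PAIRS = {
    (0, 1): 1.9, (0, 2): 1.5, (0, 3): 1.2,
    (1, 2): 1.4, (1, 3): 1.1, (2, 3): 1.8,
}


class TestAcquisition:
    def test_singleton_is_zero(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        assert acquisition.acquisition(m, Batch(indices=(2,))) == 0.0

    def test_pair_is_single_entry(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        assert acquisition.acquisition(m, Batch(indices=(0, 2))) == pytest.approx(1.5)

    def test_triple_sums_pairs(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        assert acquisition.acquisition(m, Batch(indices=(0, 1, 2))) == pytest.approx(4.8)

    def test_invariant_to_index_ordering(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        a = acquisition.acquisition(m, Batch(indices=(2, 0, 3)))
        b = acquisition.acquisition(m, Batch(indices=(3, 2, 0)))
        assert a == b


class TestSelectBatch:
    def test_best_pair_matches_brute_force(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        batch = select_batch(m, batch_size=2, method="exhaustive")
        assert batch.indices == (0, 1) and batch.score == pytest.approx(1.9)

    def test_best_triple_matches_brute_force(self):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        batch = select_batch(m, batch_size=3, method="exhaustive")
        assert batch.indices == (0, 1, 2) and batch.score == pytest.approx(4.8)

    @pytest.mark.parametrize("method", ["greedy", "exhaustive", "random"])
    def test_full_universe_forced(self, method):
        m = _matrix_from_pairs(4, FOUR_PAIRS)
        batch = select_batch(m, batch_size=4, method=method, seed=0)
        assert batch.indices == (0, 1, 2, 3)

    def test_exhaustive_budget_error_advises_greedy(self):
        m = EntropyMatrix(H=np.ones((60, 60)))
        with pytest.raises(ValueError, match="greedy"):
            select_batch(m, batch_size=10, method="exhaustive")

    def test_greedy_matches_exhaustive_on_most_instances(self):
        """Greedy-with-swap tracks the exhaustive argmax and never exceeds it."""
        rng = np.random.default_rng(7)
        matches = 0
        for _ in range(200):
            n = int(rng.integers(5, 11))
            k = int(rng.integers(2, 5))
            m = build_entropy_matrix(random_posterior(rng, n, n_draws=25))
            best = select_batch(m, batch_size=k, method="exhaustive")
            greedy = select_batch(m, batch_size=k, method="greedy")
            assert greedy.score <= best.score + 1e-9
            if greedy.score == pytest.approx(best.score, abs=1e-9):
                matches += 1
        assert matches >= 180  # at least 90% of instances

    def test_greedy_beats_random_in_expectation(self):
        rng = np.random.default_rng(13)
        greedy_vals, random_vals = [], []
        for i in range(100):
            m = build_entropy_matrix(random_posterior(rng, 15, n_draws=25))
            greedy_vals.append(select_batch(m, batch_size=5, method="greedy").score)
            random_vals.append(select_batch(m, batch_size=5, method="random", seed=i).score)
        assert np.mean(greedy_vals) >= np.mean(random_vals)

    def test_deterministic_candidate_adds_batch_marginals(self):
        """A certain candidate contributes sum of the batch's marginal entropies."""
        rng = np.random.default_rng(3)
        probs = np.vstack([rng.random((4, 30)), np.ones((1, 30))])
        m = build_entropy_matrix(PosteriorSamples(probs=probs))
        base = acquisition.acquisition(m, Batch(indices=(0, 1, 2, 3)))
        grown = acquisition.acquisition(m, Batch(indices=(0, 1, 2, 3, 4)))
        marginals = sum(m.H[j, j] for j in range(4))
        assert grown - base == pytest.approx(marginals, abs=1e-9)
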