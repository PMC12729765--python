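"""Similarity, soft targets, KL objective and prompt-ensemble classification."""

import numpy as np
import pytest

from ceusalnm.autodiff import Tensor, l2_normalize
from ceusalnm.contrastive import (
    classify,
    kl_contrastive_loss,
    predict_class,
    similarity_matrix,
    target_distribution,
)
from ceusalnm.nn import AdamW, Linear


class TestSimilarityMatrix:
    def test_orthonormal_rows_closed_form(self):
        V = Tensor(np.eye(2))
        batch = similarity_matrix(V, V, tau=1.0)
        expected = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        np.testing.assert_allclose(batch.p_x2y.data[0], expected, atol=1e-12)
        np.testing.assert_allclose(batch.p_x2y.data[0], [0.731, 0.269], atol=1e-3)

    def test_large_tau_approaches_identity(self):
        V = Tensor(np.eye(3))
        batch = similarity_matrix(V, V, tau=200.0)
        np.testing.assert_allclose(batch.p_x2y.data, np.eye(3), atol=1e-12)

    def test_rows_stochastic(self, rng):
        V = Tensor(rng.normal(size=(5, 8)))
        V = l2_normalize(V)
        T = l2_normalize(Tensor(rng.normal(size=(5, 8))))
        batch = similarity_matrix(V, T, tau=7.0)
        np.testing.assert_allclose(batch.p_x2y.data.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(batch.p_y2x.data.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        V = l2_normalize(Tensor(rng.normal(size=(4, 6))))
        T = l2_normalize(Tensor(rng.normal(size=(4, 6))))
        perm = [2, 0, 3, 1]
        S = similarity_matrix(V, T, tau=3.0).S.data
        S_perm = similarity_matrix(V, Tensor(T.data[perm]), tau=3.0).S.data
        np.testing.assert_allclose(S_perm, S[:, perm], atol=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(Tensor(np.eye(2) * 2.0), Tensor(np.eye(2)), tau=1.0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(Tensor(np.eye(2)), Tensor(np.eye(2)), tau=0.0)


class TestTargetDistribution:
    def test_distinct_labels_identity(self):
        np.testing.assert_array_equal(target_distribution([0, 1]).q_x2y, np.eye(2))

    def test_same_labels_uniform(self):
        np.testing.assert_array_equal(
            target_distribution([0, 0]).q_x2y, np.full((2, 2), 0.5)
        )

    def test_block_structure(self):
        q = target_distribution([0, 0, 1, 1]).q_x2y
        expected = np.zeros((4, 4))
        expected[:2, :2] = 0.5
        expected[2:, 2:] = 0.5
        np.testing.assert_array_equal(q, expected)

    def test_directions_are_transposes(self):
        t = target_distribution([0, 1, 0, 1, 1])
        np.testing.assert_array_equal(t.q_y2x, t.q_x2y.T)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            target_distribution([0])


class TestKlContrastiveLoss:
    def test_zero_when_p_equals_q(self):
        # all same label -> q uniform; V=T identical rows -> p uniform
        V = Tensor(np.tile([1.0, 0.0], (3, 1)))
        batch = similarity_matrix(V, V, tau=5.0)
        targets = target_distribution([1, 1, 1])
        assert kl_contrastive_loss(batch, targets).item() == pytest.approx(0.0, abs=1e-6)

    def test_hand_derived_orthonormal_case(self):
        """B=2, q=I, p rows softmax([1,0]): loss = -log 0.731 = 0.3133."""
        V = Tensor(np.eye(2))
        batch = similarity_matrix(V, V, tau=1.0)
        targets = target_distribution([0, 1])
        assert kl_contrastive_loss(batch, targets).item() == pytest.approx(0.3133, abs=1e-3)

    def test_nonnegative(self, rng):
        for _ in range(10):
            V = l2_normalize(Tensor(rng.normal(size=(4, 8))))
            T = l2_normalize(Tensor(rng.normal(size=(4, 8))))
            batch = similarity_matrix(V, T, tau=10.0)
            targets = target_distribution(rng.integers(0, 2, size=4))
            assert kl_contrastive_loss(batch, targets).item() >= -1e-9

    def test_transposition_symmetry(self, rng):
        """Swapping the roles of videos and texts leaves the loss unchanged."""
        V = l2_normalize(Tensor(rng.normal(size=(4, 8))))
        T = l2_normalize(Tensor(rng.normal(size=(4, 8))))
        labels = [0, 1, 1, 0]
        a = kl_contrastive_loss(similarity_matrix(V, T, 5.0), target_distribution(labels))
        b = kl_contrastive_loss(similarity_matrix(T, V, 5.0), target_distribution(labels))
        assert a.item() == pytest.approx(b.item(), abs=1e-10)

    def test_finite_under_mismatch(self):
        V = Tensor(np.eye(2))
        batch = similarity_matrix(V, Tensor(np.eye(2)[::-1].copy()), tau=100.0)
        loss = kl_contrastive_loss(batch, target_distribution([0, 1]))
        assert np.isfinite(loss.item())


class TestClassify:
    def test_matching_prompt_wins(self):
        e0 = np.array([[1.0, 0.0]])
        e1 = np.array([[0.0, 1.0]])
        probs = classify(np.array([0.0, 1.0]), [e0, e1], tau=5.0)
        assert probs[1] > 0.5
        assert predict_class(probs) == 1

    def test_identical_ensembles_symmetric(self):
        e = np.array([[1.0, 0.0], [0.0, 1.0]])
        probs = classify(np.array([0.6, 0.8]), [e, e], tau=5.0)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)
        assert predict_class(probs) == 0  # tie goes to class 0

    def test_hand_computed_two_by_three(self):
        """2 classes x 3 prompts, hand-evaluated mean-cosine softmax."""
        v = np.array([1.0, 0.0])
        c0 = np.array([[1.0, 0.0], [0.0, 1.0], [np.sqrt(0.5), np.sqrt(0.5)]])
        c1 = np.array([[-1.0, 0.0], [0.0, -1.0], [1.0, 0.0]])
        s0 = (1.0 + 0.0 + np.sqrt(0.5)) / 3
        s1 = (-1.0 + 0.0 + 1.0) / 3
        tau = 2.0
        expected = np.exp(tau * np.array([s0, s1]))
        expected /= expected.sum()
        np.testing.assert_allclose(classify(v, [c0, c1], tau=tau), expected, atol=1e-12)

    def test_mean_semantics_not_duplicate_invariant(self):
        """Pinned behaviour: mean aggregation, so duplicating a weak prompt
        shifts the class score (max aggregation would be invariant)."""
        v = np.array([1.0, 0.0])
        strong = np.array([[1.0, 0.0]])
        weak_dup = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        other = np.array([[0.0, -1.0]])
        p_single = classify(v, [np.array([[1.0, 0.0], [0.0, 1.0]]), other], tau=3.0)
        p_dup = classify(v, [weak_dup, other], tau=3.0)
        assert not np.allclose(p_single, p_dup)
        # under max aggregation duplication is irrelevant
        m_single = classify(v, [np.array([[1.0, 0.0], [0.0, 1.0]]), other], tau=3.0, aggregate="max")
        m_dup = classify(v, [weak_dup, other], tau=3.0, aggregate="max")
        np.testing.assert_allclose(m_single, m_dup, atol=1e-12)

    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError):
            classify(np.array([1.0, 0.0]), [np.zeros((0, 2)), np.eye(2)])


def test_linearly_separable_task_loss_halves():
    """200 optimisation steps on a separable embedding task (encoders
    bypassed, a single linear map trains) cut the loss by at least half."""
    rng = np.random.default_rng(0)
    d = 8
    centers = np.stack([np.eye(d)[0], np.eye(d)[1]])
    labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    raw = centers[labels] + 0.05 * rng.normal(size=(8, d))
    texts = centers[labels]
    lin = Linear(d, d, rng)
    opt = AdamW(lin.parameters(), lr=1e-2, weight_decay=0.0)
    losses = []
    for _ in range(200):
        V = l2_normalize(lin(Tensor(raw)))
        T = l2_normalize(Tensor(texts))
        loss = kl_contrastive_loss(
            similarity_matrix(V, T, tau=10.0), target_distribution(labels)
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert losses[-1] <= 0.5 * losses[0]
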