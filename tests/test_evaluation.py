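"""Folds, metrics, ROC, decision curves and the training loop."""

import numpy as np
import pytest

from ceusalnm.evaluation import (
    TrainConfig,
    compute_metrics,
    decision_curve,
    make_folds,
    roc_auc,
    train_fold,
)
from ceusalnm.model import ModelConfig


def brute_force_auc(y_true, y_score):
    """Pair-counting (Mann-Whitney) oracle with tie correction."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMakeFolds:
    def test_balanced_ten_patients(self):
        ids = [f"p{i}" for i in range(10)]
        labels = [0] * 5 + [1] * 5
        fa = make_folds(ids, labels, k=5, seed=0)
        for fold in fa.folds():
            assert len(fold) == 2
            assert sorted(labels[ids.index(p)] for p in fold) == [0, 1]

    def test_six_four_split(self):
        ids = [f"p{i}" for i in range(10)]
        labels = [0] * 6 + [1] * 4
        fa = make_folds(ids, labels, k=5, seed=3)
        per_fold = [[labels[ids.index(p)] for p in fold] for fold in fa.folds()]
        ones = sorted(f.count(1) for f in per_fold)
        zeros = sorted(f.count(0) for f in per_fold)
        assert ones == [0, 1, 1, 1, 1]
        assert zeros == [1, 1, 1, 1, 2]

    def test_partition(self):
        ids = [f"p{i}" for i in range(23)]
        labels = ([0, 1] * 12)[:23]
        fa = make_folds(ids, labels, k=5, seed=1)
        all_assigned = [p for fold in fa.folds() for p in fold]
        assert sorted(all_assigned) == sorted(ids)

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(12)]
        labels = [0, 1] * 6
        a = make_folds(ids, labels, k=4, seed=9)
        b = make_folds(ids, labels, k=4, seed=9)
        assert a == b

    def test_small_class_warns(self):
        with pytest.warns(UserWarning):
            make_folds(["a", "b", "c", "d", "e", "f"], [0, 0, 0, 0, 0, 1], k=5, seed=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c", "d", "e"], [0] * 5, k=5, seed=0)

    def test_random_configurations_partition_and_stratify(self, rng):
        """Folds always partition the cohort with class counts within one
        of the stratified ideal."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(2, 6))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            ids = [f"p{i}" for i in range(n)]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fa = make_folds(ids, labels, k=k, seed=int(rng.integers(1 << 30)))
            assigned = [p for fold in fa.folds() for p in fold]
            assert sorted(assigned) == sorted(ids)
            for cls in (0, 1):
                counts = [
                    sum(labels[ids.index(p)] == cls for p in fold) for fold in fa.folds()
                ]
                ideal = (labels == cls).sum() / k
                assert all(abs(c - ideal) <= 1.0 for c in counts)


class TestComputeMetrics:
    def test_perfect_scores(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.9, 0.8])
        for value in (m.sensitivity, m.specificity, m.accuracy, m.precision, m.f1, m.auc):
            assert value == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        """TP=3 FN=1 TN=4 FP=2 -> Sen .75 Spe .6667 Acc .7 Pre .6 F1 .6667."""
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_score = [0.9, 0.8, 0.7, 0.2, 0.6, 0.55, 0.3, 0.2, 0.1, 0.05]
        m = compute_metrics(y_true, y_score, threshold=0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 4, 2)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.6667, abs=1e-4)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.6)
        assert m.f1 == pytest.approx(0.6667, abs=1e-4)

    def test_flip_swaps_sensitivity_specificity(self, rng):
        y_true = np.array([0, 1] * 10)
        y_score = rng.random(20)
        m = compute_metrics(y_true, y_score)
        flipped = compute_metrics(1 - y_true, 1.0 - y_score + 1e-9)
        assert flipped.sensitivity == pytest.approx(m.specificity)
        assert flipped.specificity == pytest.approx(m.sensitivity)

    def test_zero_division_flagged(self):
        m = compute_metrics([0, 0, 1], [0.1, 0.2, 0.3], threshold=0.5)
        assert m.precision == 0.0 and m.zero_division

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1], [0.5, 0.6])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_chance_level(self):
        auc, _, _ = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_worked_example(self):
        auc, _, _ = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self, rng):
        """Trapezoidal AUC equals the Mann-Whitney pair-counting oracle
        (ties averaged) on 100 random score vectors."""
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y_true = rng.integers(0, 2, size=n)
            if y_true.sum() in (0, n):
                y_true[0] = 1 - y_true[0]
            y_score = np.round(rng.random(n), 2)  # induce ties
            auc, _, _ = roc_auc(y_true, y_score)
            assert auc == pytest.approx(brute_force_auc(y_true, y_score), abs=1e-9)


class TestDecisionCurve:
    def test_treat_none_identically_zero(self, rng):
        curve = decision_curve(rng.integers(0, 2, 20), rng.random(20))
        assert (curve.treat_none == 0).all()

    def test_hand_computed_net_benefit(self):
        """TP=8, FP=2, N=20 at p_t=0.2 -> NB = 0.4 - 0.1 * 0.25 = 0.375."""
        y_true = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        y_score = np.array([0.9] * 8 + [0.9] * 2 + [0.1] * 2 + [0.1] * 8)
        curve = decision_curve(y_true, y_score, thresholds=[0.2])
        assert curve.net_benefit[0] == pytest.approx(0.375)

    def test_treat_all_zero_at_prevalence(self):
        y_true = np.array([1] * 6 + [0] * 14)
        prevalence = 0.3
        curve = decision_curve(y_true, np.linspace(0, 1, 20), thresholds=[prevalence])
        assert curve.treat_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0, 1], [0.2, 0.8], thresholds=[0.0, 0.5])
        with pytest.raises(ValueError):
            decision_curve([0, 1], [0.2, 0.8], thresholds=[1.0])


@pytest.fixture(scope="module")
def tiny_setup():
    mc = ModelConfig(embed_dim=16, d_shared=16, n_layers=1, n_heads=2,
                     frame_size=(32, 32), patch_size=16, context_length=24)
    tc = TrainConfig(min_epochs=3, max_epochs=3, lr=3e-4, seed=0)
    return mc, tc


class TestTrainFold:

    def test_history_and_loss_decrease(self, small_dataset, tiny_setup):
        mc, tc = tiny_setup
        train, val = small_dataset[:8], small_dataset[8:]
        model, hist = train_fold(train, val, mc, tc)
        assert len(hist.train_loss) >= tc.min_epochs
        assert len(hist.val_loss) == len(hist.train_loss)
        assert all(np.isfinite(hist.train_loss))

    def test_patient_overlap_rejected(self, small_dataset, tiny_setup):
        mc, tc = tiny_setup
        with pytest.raises(ValueError, match="overlap"):
            train_fold(small_dataset[:6], small_dataset[5:], mc, tc)

    def test_empty_split_rejected(self, small_dataset, tiny_setup):
        mc, tc = tiny_setup
        with pytest.raises(ValueError):
            train_fold(small_dataset, [], mc, tc)

    def test_batch_size_one_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1)

    def test_loss_decreases_in_moving_average(self, small_dataset, tiny_setup):
        """Over the first 10 epochs on synthetic clips the training loss
        decreases in moving average (not necessarily monotonically)."""
        mc, tc = tiny_setup
        from dataclasses import replace

        tc = replace(tc, min_epochs=10, max_epochs=10, lr=6e-4, seed=0)
        _, hist = train_fold(small_dataset[:8], small_dataset[8:], mc, tc)
        first = np.mean(hist.train_loss[:3])
        last = np.mean(hist.train_loss[-3:])
        assert last < first
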