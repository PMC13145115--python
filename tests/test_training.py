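"""Metric oracles, paired comparison, fold construction and training-loop
contracts."""

import numpy as np
import pytest

from transbind import (
    ModelConfig,
    TrainConfig,
    TransBindModel,
    loto_folds,
    paired_compare,
    per_label_metrics,
    train,
)
from transbind.training import bce_with_logits
from transbind.nn import Tensor


# ------------------------------------------------------- brute-force oracles


def auroc_bruteforce(scores, labels):
    """Probability a random positive outranks a random negative; ties 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_bruteforce(scores, labels):
    """Step-wise PR integral: sum over distinct thresholds of
    (recall gain) * precision at that threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        selected = scores >= thr
        tp = int(labels[selected].sum())
        precision = tp / selected.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestMetricExamples:
    def test_perfect_separation(self):
        mt = per_label_metrics(np.array([0.9, 0.8, 0.2, 0.1]),
                               np.array([1, 1, 0, 0]))
        assert mt.macro_auroc == 1.0 and mt.macro_aupr == 1.0

    def test_perfectly_wrong(self):
        mt = per_label_metrics(np.array([0.9, 0.1]), np.array([0, 1]))
        assert mt.macro_auroc == 0.0

    def test_hand_walked_pr_curve(self):
        mt = per_label_metrics(np.array([0.8, 0.6, 0.4, 0.2]),
                               np.array([1, 0, 1, 0]))
        assert mt.macro_auroc == pytest.approx(0.75)
        assert mt.macro_aupr == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)

    def test_constant_scores_give_half_auroc(self):
        mt = per_label_metrics(np.full(10, 0.5),
                               np.array([1, 0] * 5))
        assert mt.macro_auroc == pytest.approx(0.5)

    def test_degenerate_labels_skipped_and_reported(self):
        scores = np.random.default_rng(0).random((6, 3))
        labels = np.zeros((6, 3), dtype=int)
        labels[:3, 0] = 1  # only label 0 has both classes
        labels[:, 2] = 1  # label 2 all positive
        mt = per_label_metrics(scores, labels, ["a", "b", "c"])
        assert mt.skipped == ["b", "c"]
        assert np.isnan(mt.auroc[1]) and np.isnan(mt.auroc[2])

    def test_all_labels_degenerate_errors(self):
        with pytest.raises(ValueError):
            per_label_metrics(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            per_label_metrics(np.array([0.1, 0.2]), np.array([0, 2]))


class TestMetricOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        mt = per_label_metrics(scores, labels)
        assert mt.macro_auroc == pytest.approx(
            auroc_bruteforce(scores, labels), abs=1e-9)
        assert mt.macro_aupr == pytest.approx(
            average_precision_bruteforce(scores, labels), abs=1e-9)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[0], labels[1] = 0, 1
        a = per_label_metrics(scores, labels).macro_auroc
        b = per_label_metrics(np.exp(3 * scores) + 7, labels).macro_auroc
        assert a == pytest.approx(b, abs=1e-12)


class TestPairedCompare:
    def test_identical_vectors(self):
        r = paired_compare(np.array([0.5, 0.6, 0.7]),
                           np.array([0.5, 0.6, 0.7]))
        assert r.degenerate and r.t_statistic == 0.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_compare(np.array([2.0, 3.0, 4.0]),
                           np.array([1.0, 2.0, 3.0]))
        assert r.degenerate

    def test_hand_computed_cohens_d(self):
        a = np.array([1.1, 1.3, 1.2])
        b = np.array([1.0, 1.0, 1.0])
        r = paired_compare(a, b)  # diffs 0.1, 0.3, 0.2 -> d = 0.2 / 0.1
        assert r.cohens_d == pytest.approx(2.0)
        assert r.n_pairs == 3

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(20), rng.random(20)
        r1, r2 = paired_compare(a, b), paired_compare(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a = rng.random(30)
        b = a + rng.normal(0.05, 0.1, size=30)
        r = paired_compare(a, b)
        t, p = stats.ttest_rel(a, b)
        assert r.t_statistic == pytest.approx(float(t))
        assert r.p_value == pytest.approx(float(p))


class TestLotoFolds:
    def test_every_tf_held_out_once(self):
        names = [f"tf{i}" for i in range(12)]
        folds = loto_folds(names, fold_size=3, n_folds=4, seed=0)
        held = [tf for _, h in folds for tf in h]
        assert sorted(held) == sorted(names)

    def test_eight_folds_cover_24_tfs(self):
        names = [f"tf{i}" for i in range(161)]
        folds = loto_folds(names, fold_size=3, n_folds=8, seed=1)
        held = {tf for _, h in folds for tf in h}
        assert len(held) == 24

    def test_no_leakage_between_train_and_heldout(self):
        folds = loto_folds([f"tf{i}" for i in range(20)], 3, 5, seed=2)
        for train_tfs, held in folds:
            assert not set(train_tfs) & set(held)
            assert len(train_tfs) + len(held) == 20

    def test_deterministic(self):
        names = [f"tf{i}" for i in range(30)]
        assert loto_folds(names, 3, 8, seed=9) == loto_folds(names, 3, 8, seed=9)

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError):
            loto_folds(["a", "b"], fold_size=2, n_folds=2)


def micro_problem(seed=0):
    cfg = ModelConfig(
        input_len=60, conv_filters=6, conv_kernel=6, pool_window=5,
        lstm_hidden_per_dir=4, lstm_layers=1, transformer_heads=2,
        transformer_ffn=8, d2=8, cross_attn_heads=2, dropout_p=0.0,
        n_labels=2, seed=seed,
    ).validate()
    rng = np.random.default_rng(seed)
    emb = rng.normal(size=(2, 8))
    X = rng.integers(0, 2, size=(24, 60, 4)).astype(float)
    Y = (X[:, :30, 0].mean(axis=1, keepdims=True) >
         X[:, 30:, 1].mean(axis=1, keepdims=True)).astype(float)
    Y = np.concatenate([Y, 1 - Y], axis=1)
    data = {"train": {"X": X, "Y": Y}, "val": {"X": X[:8], "Y": Y[:8]}}
    return cfg, emb, data


class TestTrainLoop:
    def test_zero_lr_leaves_parameters_unchanged(self):
        cfg, emb, data = micro_problem()
        model = TransBindModel(cfg, emb)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        train(model, data, TrainConfig(lr=0.0, max_epochs=1, batch_size=8))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_seeded_runs_identical(self):
        losses = []
        for _ in range(2):
            cfg, emb, data = micro_problem(seed=3)
            model = TransBindModel(cfg, emb)
            out = train(model, data,
                        TrainConfig(lr=1e-3, max_epochs=3, batch_size=8,
                                    seed=5))
            losses.append(out["history"][-1]["train_loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_loss_decreases_on_learnable_problem(self):
        cfg, emb, data = micro_problem(seed=4)
        model = TransBindModel(cfg, emb)
        out = train(model, data,
                    TrainConfig(lr=3e-3, weight_decay=0.0, max_epochs=10,
                                batch_size=8, seed=0))
        h = out["history"]
        assert h[-1]["train_loss"] < h[0]["train_loss"]

    def test_empty_dataset_errors(self):
        cfg, emb, _ = micro_problem()
        model = TransBindModel(cfg, emb)
        empty = {"train": {"X": np.zeros((0, 60, 4)), "Y": np.zeros((0, 2))}}
        with pytest.raises(ValueError):
            train(model, empty, TrainConfig(max_epochs=1))

    def test_bce_matches_manual_formula(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 3)) * 5
        y = rng.integers(0, 2, size=(4, 3)).astype(float)
        loss = bce_with_logits(Tensor(z), y).item()
        p = 1 / (1 + np.exp(-z))
        manual = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert loss == pytest.approx(manual, abs=1e-9)
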