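"""CNN training: sampler balance, determinism, learning, transfer contracts."""

from __future__ import annotations

import numpy as np
import pytest

import ctcvision as cv
from ctcvision.model_train import examples_to_arrays


def collect_batches(labels, batch_size, seed=0):
    rng = np.random.default_rng(seed)
    return list(cv.balanced_minibatches(np.asarray(labels), batch_size, rng))


class TestBalancedMinibatches:
    def test_already_balanced_pool(self):
        labels = [1] * 10 + [0] * 10
        batches = collect_batches(labels, 4)
        assert len(batches) == 5
        for b in batches:
            assert sum(labels[i] for i in b) == 2

    def test_imbalanced_pool_exact_balance(self):
        """91 tumor / 308 healthy at batch 14: 44 batches, each exactly 7/7."""
        labels = np.array([1] * 91 + [0] * 308)
        batches = collect_batches(labels, 14, seed=3)
        assert len(batches) == 44
        seen = []
        for b in batches:
            assert len(b) == 14
            assert labels[b].sum() == 7
            seen.extend(b)
        assert np.mean(labels[seen]) == 0.5  # epoch-level class ratio exactly 1/2
        # the majority class is swept: every healthy example appears
        majority_seen = {i for i in seen if labels[i] == 0}
        assert len(majority_seen) == 308

    def test_table_scale_imbalance(self):
        """~1:3.4 imbalance (the emulated 9106:30785) still balances batches."""
        n_tum, n_non = 91, 308  # same ratio at 1/100 scale
        labels = np.array([1] * n_tum + [0] * n_non)
        for b in collect_batches(labels, 32, seed=1):
            assert labels[b].sum() == len(b) // 2

    def test_absent_class_named_in_error(self):
        with pytest.raises(ValueError, match="tumor"):
            collect_batches([0, 0, 0, 0], 2)
        with pytest.raises(ValueError, match="non-tumor"):
            collect_batches([1, 1, 1, 1], 2)

    def test_odd_batch_rejected(self):
        with pytest.raises(ValueError):
            collect_batches([0, 1], 3)

    def test_all_data_mode_preserves_ratio(self):
        labels = np.array([1] * 91 + [0] * 308)
        rng = np.random.default_rng(5)
        seen = np.concatenate(list(cv.all_data_batches(labels, 32, rng)))
        assert len(seen) == 399
        assert abs(labels[seen].mean() - 91 / 399) < 0.02  # exact, in fact


class TestBuildModel:
    def test_same_seed_identical_parameters(self):
        a = cv.build_model(seed=4)
        b = cv.build_model(seed=4)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_softmax_contract_untrained(self, rng):
        model = cv.build_model(seed=0)
        x = rng.random((5, 1, 32, 32), dtype=np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_bad_architecture_rejected(self):
        with pytest.raises(ValueError):
            cv.build_model(arch_spec=[{"type": "dense", "units": 2}])  # not flattened
        with pytest.raises(ValueError):
            cv.build_model((1, 2, 2), arch_spec=[{"type": "conv", "filters": 4, "kernel": 3}])
        with pytest.raises(ValueError):  # must end in 2-way output
            cv.build_model(arch_spec=[{"type": "flatten"}, {"type": "dense", "units": 3}])


class TestTraining:
    def test_zero_epochs_leaves_predictions_unchanged(self, separable_crops):
        model = cv.build_model(seed=1)
        x, _ = examples_to_arrays(separable_crops[:20])
        before = model.predict_proba(x)
        trained = cv.pretrain(model, separable_crops,
                              cv.TrainConfig(epochs=0, seed=1))
        np.testing.assert_array_equal(trained.predict_proba(x), before)

    def test_separable_fixture_trains_to_high_accuracy(self, separable_crops):
        """Strong-contrast, low-noise classes: 25 epochs reach >=0.99 train accuracy."""
        model = cv.build_model(seed=2)
        cfg = cv.TrainConfig(epochs=25, seed=2)
        trained = cv.pretrain(model, separable_crops, cfg)
        x, y = examples_to_arrays(separable_crops)
        labels, _ = cv.predict(trained, x)
        assert cv.accuracy(labels, y) >= 0.99

    def test_loss_decreases_early(self, separable_crops):
        model = cv.build_model(seed=3)
        trained = cv.pretrain(model, separable_crops, cv.TrainConfig(epochs=5, seed=3))
        losses = [h["loss"] for h in trained.history]
        # monotone apart from at most one step
        violations = sum(b > a for a, b in zip(losses, losses[1:]))
        assert violations <= 1

    def test_seeded_end_to_end_determinism(self, separable_crops):
        runs = []
        for _ in range(2):
            model = cv.build_model(seed=9)
            trained = cv.pretrain(model, separable_crops[:100],
                                  cv.TrainConfig(epochs=3, seed=9))
            runs.append([h["loss"] for h in trained.history])
        assert runs[0] == runs[1]

    def test_balanced_mode_improves_minority_recall(self):
        """On a 1:9 imbalanced pool, balanced batches lift minority recall."""
        spec = cv.SceneSpec(n_tumor=4, n_leukocyte=36, seed=50)
        crops = cv.generate_dataset(spec, 12, imbalance_ratio=1 / 9)
        x, y = examples_to_arrays(crops)
        recalls = {}
        for mode in ("balanced_minibatch", "all_data"):
            rec = []
            for seed in range(5):
                model = cv.build_model(seed=seed)
                cfg = cv.TrainConfig(epochs=8, sampling_mode=mode, seed=seed)
                trained = cv.pretrain(model, crops, cfg)
                labels, _ = cv.predict(trained, x)
                rec.append(labels[y == 1].mean())
            recalls[mode] = np.mean(rec)
        assert recalls["balanced_minibatch"] >= recalls["all_data"]

    def test_missing_class_rejected(self, separable_crops):
        only_tumor = [c for c in separable_crops if c.label == 1]
        with pytest.raises(ValueError, match="absent"):
            cv.pretrain(cv.build_model(seed=0), only_tumor, cv.TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def pretrained(separable_crops):
    model = cv.build_model(seed=5)
    return cv.pretrain(model, separable_crops, cv.TrainConfig(epochs=6, seed=5))


class TestFineTune:
    def test_zero_examples_returns_pretrained_predictions(self, pretrained, separable_crops):
        x, _ = examples_to_arrays(separable_crops[:10])
        tuned = cv.fine_tune(pretrained, [], cv.TrainConfig(epochs=5))
        np.testing.assert_array_equal(tuned.predict_proba(x), pretrained.predict_proba(x))

    def test_single_image_fine_tuning_runs(self, pretrained, separable_crops):
        tuned = cv.fine_tune(
            pretrained, separable_crops[:1],
            cv.TrainConfig(epochs=2, sampling_mode="all_data", seed=1),
        )
        assert tuned is not pretrained
        assert tuned.history[-1]["phase"] == "finetune"

    def test_transfer_preserves_architecture(self, pretrained, separable_crops):
        tuned = cv.fine_tune(pretrained, separable_crops[:8],
                             cv.TrainConfig(epochs=1, sampling_mode="all_data"))
        assert tuned.param_shapes() == pretrained.param_shapes()

    def test_pretrained_model_not_mutated(self, pretrained, separable_crops):
        before = pretrained.get_weights()
        cv.fine_tune(pretrained, separable_crops[:8],
                     cv.TrainConfig(epochs=2, sampling_mode="all_data"))
        for a, b in zip(before, pretrained.get_weights()):
            np.testing.assert_array_equal(a, b)


class TestPredictAccuracy:
    def test_perfect_and_flipped(self):
        truth = np.array([0, 1, 1, 0])
        assert cv.accuracy(truth, truth) == 1.0
        assert cv.accuracy(1 - truth, truth) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cv.accuracy(np.array([]), np.array([]))

    def test_random_stub_near_half(self):
        """Uniform random classifier on a balanced set: within 3 binomial SE of 0.5."""
        from conftest import StubModel

        n = 2000
        truth = np.arange(n) % 2
        stub = StubModel(mode="random", seed=8)
        probs = stub.predict_proba(np.zeros((n, 1)))
        acc = cv.accuracy(probs.argmax(axis=1), truth)
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_gradient_against_numerical_check(self, rng):
        """Backprop through the full stack matches finite differences."""
        from ctcvision import nn

        model = cv.build_model((1, 8, 8),
                               arch_spec=[
                                   {"type": "conv", "filters": 2, "kernel": 3},
                                   {"type": "relu"},
                                   {"type": "pool"},
                                   {"type": "flatten"},
                                   {"type": "dense", "units": 2},
                               ], seed=1)
        x = rng.random((3, 1, 8, 8), dtype=np.float32).astype(np.float64).astype(np.float32)
        y = np.array([0, 1, 0])
        logits = model.forward(x, train=True)
        _, grad = nn.cross_entropy_grad(logits, y)
        model.backward(grad)
        layer = model.layers[0]
        analytic = layer.dw[0, 0]
        eps = 1e-3
        w = layer.w
        w[0, 0] += eps
        lp, _ = nn.cross_entropy_grad(model.forward(x, train=True), y)
        w[0, 0] -= 2 * eps
        lm, _ = nn.cross_entropy_grad(model.forward(x, train=True), y)
        w[0, 0] += eps
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.05, abs=1e-4)
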