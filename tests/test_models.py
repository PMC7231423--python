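import math

import numpy as np
import pytest

import szdetect as sz
from szdetect.models import (ModelSpec, TrainConfig, WeightsUnavailableError,
                             build_model, reference_recipe)


class TestSoftmaxCrossEntropy:
    @pytest.mark.parametrize("r,p,expected", [
        ((1, 0), (1, 0), 0.0),
        ((1, 0), (0.5, 0.5), math.log(2)),
        ((0.3, 0.7), (0.6, 0.4), -(0.3 * math.log(0.6) + 0.7 * math.log(0.4))),
    ])
    def test_analytic_values(self, r, p, expected):
        assert sz.softmax_cross_entropy(r, p) == pytest.approx(expected,
                                                               abs=1e-9)

    def test_rejects_non_normalized_vectors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sz.softmax_cross_entropy((0.5, 0.4), (0.5, 0.5))
        with pytest.raises(ValueError, match="lie in"):
            sz.softmax_cross_entropy((1.5, -0.5), (0.5, 0.5))

    def test_agrees_with_independent_scalar_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            r1, p1 = rng.uniform(0, 1), rng.uniform(1e-6, 1 - 1e-6)
            got = sz.softmax_cross_entropy((r1, 1 - r1), (p1, 1 - p1))
            want = -(r1 * math.log(p1) + (1 - r1) * math.log(1 - p1))
            assert abs(got - want) < 1e-9


class TestBuildModel:
    def test_trainable_parameter_count_closed_form_vgg16(self):
        model = build_model(ModelSpec(backbone="vgg16",
                                      fc_sizes=(4096, 4096)))
        pooled = 7 * 7 * 512
        expected = (pooled * 4096 + 4096 + 4096 * 4096 + 4096
                    + 4096 * 2 + 2)
        assert model.pooled_dim == pooled
        assert model.trainable_parameter_count() == expected
        # the framework's own per-array summary agrees
        assert sum(p.size for p in model.head.parameters()) == expected

    def test_resnet50_uses_global_average_pooling(self):
        model = build_model(ModelSpec(backbone="resnet50",
                                      fc_sizes=(2048, 2048)))
        assert model.spec.pooling == "global_average"
        assert model.pooled_dim == 2048

    def test_tiny_random_outputs_softmax_rows(self):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(32, 16)), seed=0)
        images = np.random.default_rng(0).random((4, 224, 224, 3),
                                                 dtype=np.float32)
        probs = model.predict_proba(images)
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_pretrained_request_raises_offline_error(self):
        with pytest.raises(WeightsUnavailableError, match="tiny_random"):
            build_model(ModelSpec(backbone="vgg16", pretrained=True))
        with pytest.raises(WeightsUnavailableError, match="tiny_random"):
            build_model(ModelSpec(backbone="resnet50")).features(
                np.zeros((1, 224, 224, 3), np.float32))

    def test_tiny_random_cannot_claim_pretrained_weights(self):
        with pytest.raises(ValueError, match="pretrained"):
            ModelSpec(backbone="tiny_random", pretrained=True)

    def test_reference_recipe_per_backbone(self):
        vgg = reference_recipe("vgg16")
        assert (vgg.optimizer, vgg.batch_size, vgg.lr, vgg.sgd_decay) == \
            ("sgd", 64, 1e-3, 1e-5)
        res = reference_recipe("resnet50")
        assert (res.optimizer, res.batch_size) == ("adam", 16)
        assert res.use_plateau and not vgg.use_plateau


class TestHeadGradients:
    def test_backprop_matches_finite_differences(self):
        from szdetect._nn import DenseHead

        rng = np.random.default_rng(3)
        head = DenseHead(5, (7, 4), rng=rng)
        features = rng.normal(size=(6, 5))
        y = np.eye(2)[rng.integers(0, 2, 6)]

        def loss():
            probs, _ = head.forward(features)
            return -(y * np.log(probs)).sum(axis=1).mean()

        probs, cache = head.forward(features)
        grads = head.backward(probs, cache, y)
        params = head.parameters()
        eps = 1e-6
        rng2 = np.random.default_rng(4)
        for p, g in zip(params, grads):
            for _ in range(3):
                idx = tuple(rng2.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up = loss()
                p[idx] = orig - eps
                down = loss()
                p[idx] = orig
                assert g[idx] == pytest.approx((up - down) / (2 * eps),
                                               rel=1e-4, abs=1e-7)


class TestTraining:
    @pytest.fixture()
    def split(self, small_image_bank):
        return sz.split_dataset(small_image_bank, seed=0)

    def test_learning_improves_train_accuracy(self, small_image_bank, split):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(64, 32)), seed=0)
        history = sz.train(model, small_image_bank, split,
                           TrainConfig(max_epochs=10, batch_size=16, seed=0))
        assert history.n_epochs <= 10
        assert np.isfinite(history.train_loss).all()
        assert history.train_acc[-1] > history.train_acc[0]

    def test_frozen_backbone_weights_bitwise_unchanged(self, small_image_bank,
                                                       split):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(32, 16)), seed=1)
        before = [w.copy() for w in model.backbone_parameters()]
        sz.train(model, small_image_bank, split,
                 TrainConfig(max_epochs=3, batch_size=16, seed=1))
        for b, a in zip(before, model.backbone_parameters()):
            assert np.array_equal(b, a)

    def test_early_stopping_on_flat_validation_loss(self, small_image_bank,
                                                    split):
        """A stalled optimizer (vanishing learning rate) gives a flat
        validation curve, so training must stop after exactly
        1 + patience epochs."""
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(16, 8)), seed=2)
        history = sz.train(model, small_image_bank, split,
                           TrainConfig(lr=1e-300, max_epochs=500,
                                       early_stop_patience=5, seed=2))
        assert history.stopped_early
        assert history.n_epochs == 6

    def test_training_is_deterministic_per_seed(self, small_image_bank,
                                                split):
        outs = []
        for _ in range(2):
            model = build_model(ModelSpec(backbone="tiny_random",
                                          fc_sizes=(32, 16)), seed=5)
            sz.train(model, small_image_bank, split,
                     TrainConfig(max_epochs=3, batch_size=16, seed=5))
            outs.append(model.predict_proba(
                small_image_bank.images[split.test_idx]))
        assert np.array_equal(outs[0], outs[1])

    def test_plateau_reduces_learning_rate_on_adam_path(self,
                                                        small_image_bank,
                                                        split):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(16, 8)), seed=3)
        history = sz.train(
            model, small_image_bank, split,
            TrainConfig(optimizer="adam", lr=1e-300, max_epochs=500,
                        early_stop_patience=12, plateau_patience=5, seed=3))
        # flat validation: lr cut by 0.8 after epochs 6 and 11
        assert history.lr[-1] == pytest.approx(1e-300 * 0.8 ** 2)

    def test_unfreezing_is_rejected(self, small_image_bank, split):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      freeze_backbone=False,
                                      fc_sizes=(16, 8)))
        with pytest.raises(NotImplementedError, match="freeze"):
            sz.train(model, small_image_bank, split, TrainConfig())

    def test_best_validation_weights_restored(self, small_image_bank, split):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(64, 32)), seed=4)
        history = sz.train(model, small_image_bank, split,
                           TrainConfig(max_epochs=8, batch_size=16, seed=4))
        f_val = model.features(small_image_bank.images[split.val_idx])
        probs = model.head.predict_proba(f_val)
        y = np.eye(2)[small_image_bank.labels[split.val_idx]]
        val_loss = -(y * np.log(np.clip(probs, 1e-12, 1))).sum(1).mean()
        assert val_loss == pytest.approx(min(history.val_loss), abs=1e-9)


class TestPredictAndCheckpoint:
    def test_predict_rows_sum_to_one_and_count_matches(self,
                                                       small_image_bank):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(16, 8)), seed=0)
        probs = sz.predict(model, small_image_bank.images[:7])
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_round_trip(self, small_image_bank, tmp_path):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(32, 16)), seed=6)
        path = tmp_path / "model.npz"
        model.save(path)
        back = sz.TransferModel.load(path)
        x = small_image_bank.images[:5]
        assert np.array_equal(model.predict_proba(x), back.predict_proba(x))


def test_repeat_runs_reports_and_mean(small_image_bank):
    spec = ModelSpec(backbone="tiny_random", fc_sizes=(32, 16))
    config = TrainConfig(max_epochs=5, batch_size=16)
    reports, mean = sz.repeat_runs(small_image_bank, spec, config,
                                   repeats=3, base_seed=0)
    assert len(reports) == 3
    assert mean.accuracy == pytest.approx(
        np.mean([r.accuracy for r in reports]))
    assert mean.mcor == pytest.approx(np.mean([r.mcor for r in reports]))
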