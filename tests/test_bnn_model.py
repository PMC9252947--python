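import dataclasses

import numpy as np
import pytest

from petnorm.bnn_model import (
    ModelConfig,
    ScanRecord,
    ShapeError,
    TrainConfig,
    UNet,
    _loss_and_grad,
    build_unet,
    heteroscedastic_loss,
    load_checkpoint,
    predict_batch,
    predict_distribution,
    save_checkpoint,
    train,
)
from petnorm.io_volumes import Volume, VolumePair
from petnorm.phantom import make_phantom_labels, synthesize_pair


class TestArchitecture:
    def test_output_shape_two_heads(self):
        model = build_unet(ModelConfig(depth=4, base_channels=2), seed=0)
        x = np.zeros((1, 64, 64, 1), dtype=np.float32)
        assert model.forward(x).shape == (1, 64, 64, 2)

    def test_mean_only_variant_has_one_head(self):
        model = build_unet(ModelConfig(depth=2, predict_variance=False), seed=0)
        assert model.forward(np.zeros((1, 8, 8, 1), np.float32)).shape == (1, 8, 8, 1)

    def test_indivisible_shape_raises_with_pad_guidance(self):
        model = build_unet(ModelConfig(depth=4), seed=0)
        with pytest.raises(ShapeError, match="pad"):
            model.forward(np.zeros((1, 36, 36, 1), np.float32))

    def test_deterministic_forward_without_dropout(self, rng):
        model = build_unet(ModelConfig(depth=3, dropout_rate=0.5), seed=1)
        x = rng.standard_normal((2, 16, 16, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_predicted_logvar_respects_clamp_after_training(self):
        # the training path clips s into the clamp interval before use
        cfg = ModelConfig(depth=2, logvar_clamp=(-2.0, 2.0))
        model = build_unet(cfg, seed=0)
        out = model.forward(np.zeros((1, 8, 8, 1), np.float32))
        pred = predict_batch(model, np.zeros((1, 8, 8)))
        lo, hi = np.exp(-2.0), np.exp(2.0)
        assert np.all(pred.aleatoric_variance >= lo - 1e-6)
        assert np.all(pred.aleatoric_variance <= hi + 1e-6)


class TestLoss:
    def test_zero_residual_zero_logvar_gives_zero(self):
        y = np.ones((4, 4))
        assert heteroscedastic_loss(y, np.zeros_like(y), y) == 0.0

    def test_unit_residual_gives_half(self):
        mean = np.zeros((1, 1))
        target = np.ones((1, 1))
        assert heteroscedastic_loss(mean, np.zeros((1, 1)), target) == pytest.approx(0.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            heteroscedastic_loss(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize("residual", [0.3, 1.0, 2.5])
    def test_optimal_logvar_matches_closed_form(self, residual):
        """Minimizing over s on a fine grid reproduces s* = log r^2 and
        loss 1/2 (1 + log r^2)."""
        grid = np.linspace(-10, 6, 20001)
        losses = 0.5 * np.exp(-grid) * residual**2 + 0.5 * grid
        s_star = grid[np.argmin(losses)]
        assert abs(s_star - np.log(residual**2)) < 1e-3
        assert abs(losses.min() - 0.5 * (1 + np.log(residual**2))) < 1e-3
        # and the implementation evaluates to the same values on the grid
        impl = np.array(
            [
                heteroscedastic_loss(
                    np.zeros((1, 1)), np.full((1, 1), s), np.full((1, 1), residual)
                )
                for s in grid[:: 2000]
            ]
        )
        np.testing.assert_allclose(impl, losses[::2000], atol=1e-12)


def _make_dataset(n_scans, shape=(32, 32, 4), role="train"):
    records = []
    for s in range(n_scans):
        labels = make_phantom_labels(shape, seed=s)
        pair, _ = synthesize_pair(labels, seed=s + 100)
        records.append(ScanRecord(f"scan_{s}", role, pair))
    return records


class TestTraining:
    def test_empty_dataset_rejected(self, tiny_model_config, tiny_train_config):
        model = build_unet(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            train(model, [], tiny_train_config)

    def test_abnormal_role_rejected(self, tiny_model_config, tiny_train_config):
        records = _make_dataset(2, role="eval_abnormal")
        model = build_unet(tiny_model_config, seed=0)
        with pytest.raises(ValueError, match="abnormal"):
            train(model, records, tiny_train_config)

    def test_seeded_history_reproducible(self, tiny_model_config):
        records = _make_dataset(3)
        tc = TrainConfig(epochs=2, batch_size=8, seed=5)
        _, h1 = train(build_unet(tiny_model_config, seed=2), records, tc)
        _, h2 = train(build_unet(tiny_model_config, seed=2), records, tc)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_loss_decreases(self, tiny_model_config):
        records = _make_dataset(4)
        tc = TrainConfig(epochs=10, batch_size=8, learning_rate=5e-3, seed=3)
        _, hist = train(build_unet(tiny_model_config, seed=1), records, tc)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_constant_target_reaches_analytic_floor(self):
        """On targets y ~ N(c, sigma^2) independent of the input, the NLL
        floor is 1/2 (1 + log sigma^2); training approaches it."""
        rng = np.random.default_rng(0)
        sigma = 0.3
        records = []
        for s in range(6):
            anatomy = np.zeros((16, 16, 4))
            function = 1.0 + sigma * rng.standard_normal((16, 16, 4))
            records.append(
                ScanRecord(
                    f"s{s}", "train",
                    VolumePair(Volume(anatomy), Volume(function)),
                )
            )
        cfg = ModelConfig(depth=2, base_channels=4, dropout_rate=0.0,
                          input_norm=(0.0, 1.0))
        tc = TrainConfig(epochs=100, batch_size=8, learning_rate=1e-2, seed=1)
        _, hist = train(build_unet(cfg, seed=4), records, tc)
        floor = 0.5 * (1 + np.log(sigma**2))
        assert hist.train_loss[-1] == pytest.approx(floor, abs=0.15)


class TestPredictDistribution:
    def test_t1_has_zero_epistemic(self):
        model = build_unet(ModelConfig(depth=2), seed=0)
        pred = predict_distribution(model, np.zeros((8, 8)))
        np.testing.assert_array_equal(pred.epistemic_variance, 0.0)
        np.testing.assert_allclose(
            pred.variance, np.maximum(pred.aleatoric_variance, 1e-6)
        )

    def test_invalid_mc_samples_rejected(self):
        model = build_unet(ModelConfig(depth=2), seed=0)
        with pytest.raises(ValueError):
            predict_distribution(model, np.zeros((8, 8)), mc_samples=0)

    def test_zero_dropout_sampling_equals_deterministic(self):
        model = build_unet(ModelConfig(depth=2, dropout_rate=0.0), seed=3)
        x = np.random.default_rng(0).standard_normal((8, 8))
        det = predict_distribution(model, x, mc_samples=1)
        mc = predict_distribution(model, x, mc_samples=5,
                                  rng=np.random.default_rng(1))
        np.testing.assert_allclose(mc.mean, det.mean, atol=1e-6)
        np.testing.assert_allclose(mc.epistemic_variance, 0.0, atol=1e-10)

    def test_epistemic_variance_is_population_variance_of_means(self):
        """Two stubbed samples with means {1, 3} give epistemic variance 1."""

        class StubModel:
            config = ModelConfig(depth=2, dropout_rate=0.5)
            dtype = np.float64

            def __init__(self):
                self._calls = 0

            def forward(self, x, dropout_rng=None):
                out = np.zeros(x.shape[:3] + (2,))
                out[..., 0] = 1.0 if self._calls % 2 == 0 else 3.0
                self._calls += 1
                return out

        pred = predict_batch(StubModel(), np.zeros((1, 4, 4)), mc_samples=2,
                             rng=np.random.default_rng(0))
        np.testing.assert_allclose(pred.epistemic_variance, 1.0)
        np.testing.assert_allclose(pred.mean, 2.0)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_model_config):
        model = build_unet(tiny_model_config, seed=8)
        x = np.random.default_rng(2).standard_normal((8, 8))
        before = predict_distribution(model, x)
        save_checkpoint(model, tmp_path / "m.npz", TrainConfig())
        loaded = load_checkpoint(tmp_path / "m.npz")
        after = predict_distribution(loaded, x)
        np.testing.assert_allclose(after.mean, before.mean, atol=1e-7)
        np.testing.assert_allclose(after.variance, before.variance, rtol=1e-6)
        assert loaded.config == model.config
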