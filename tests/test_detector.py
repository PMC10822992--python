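"""Detector: preprocessing, patch ops, transformer blocks, training contracts."""

import numpy as np
import pytest

from fundusvit import (
    BoundingBox, DESK_CONFIG, PAPER_CONFIG, TrainConfig, ViTDetector,
    ViTDetectorConfig, extract_patches, fine_tune, load_model, predict_box,
    preprocess, save_model, train,
)
from fundusvit.detector import (
    PatchEncoder, TransformerBlock, assemble_patches, encode_patches,
    transformer_block,
)


# ---------------------------------------------------------------- preprocess

class TestPreprocess:
    def test_downscales_to_224(self, rng):
        out = preprocess(rng.random((448, 448, 3)))
        assert out.shape == (224, 224, 3)

    def test_non_square_forced_to_square(self, rng):
        """Both sides are forced to the target: aspect ratio is not preserved."""
        out = preprocess(rng.random((300, 200, 3)))
        assert out.shape == (224, 224, 3)

    def test_constant_image_maps_to_zero(self):
        out = preprocess(np.full((224, 224, 3), 0.5))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_uint8_input_rescaled(self):
        out = preprocess(np.full((224, 224, 3), 255, dtype=np.uint8))
        np.testing.assert_allclose(out, 1.0)

    @pytest.mark.parametrize("shape", [(224, 224), (0, 224, 3), (224, 224, 4)])
    def test_invalid_inputs_rejected(self, shape):
        with pytest.raises(ValueError):
            preprocess(np.zeros(shape))


# ---------------------------------------------------------------- patch ops

class TestPatches:
    def test_reference_configuration_counts(self):
        """224 px images with 32 px patches: 49 patches of 3,072 elements."""
        assert PAPER_CONFIG.num_patches == 49
        assert PAPER_CONFIG.patch_elements == 3072
        seq = extract_patches(np.zeros((224, 224, 3)), 32)
        assert seq.patches.shape == (49, 3072)

    def test_small_configuration_counts(self, rng):
        seq = extract_patches(rng.random((64, 64, 3)), 32)
        assert seq.patches.shape == (4, 3072)

    def test_partition_is_lossless(self, rng):
        img = rng.random((64, 64, 3))
        seq = extract_patches(img, 16)
        np.testing.assert_array_equal(assemble_patches(seq, 16), img)
        assert seq.patches.sum() == pytest.approx(img.sum())

    def test_rows_are_row_major_over_grid_and_patch(self):
        img = np.arange(32 * 32 * 3, dtype=float).reshape(32, 32, 3)
        seq = extract_patches(img, 16)
        np.testing.assert_array_equal(seq.patches[0], img[:16, :16].ravel())
        np.testing.assert_array_equal(seq.patches[1], img[:16, 16:].ravel())
        np.testing.assert_array_equal(seq.patches[2], img[16:, :16].ravel())

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            extract_patches(np.zeros((50, 50, 3)), 32)


# ---------------------------------------------------------------- encoder

class TestPatchEncoder:
    def test_zero_parameters_give_zero_embeddings(self, rng):
        enc = PatchEncoder(4, 12, 8, rng)
        for k in enc.params:
            enc.params[k][:] = 0.0
        seq = extract_patches(rng.random((4, 4, 3)), 2)
        np.testing.assert_array_equal(encode_patches(seq, enc), np.zeros((4, 8)))

    def test_positional_embedding_disambiguates_identical_patches(self, rng):
        enc = PatchEncoder(4, 12, 8, rng)
        seq = extract_patches(np.ones((4, 4, 3)), 2)
        out = encode_patches(seq, enc)
        assert len({tuple(row.round(12)) for row in out}) == 4

    def test_one_hot_projection_selects_patch_elements(self, rng):
        enc = PatchEncoder(4, 12, 3, rng)
        enc.params["W"][:] = 0.0
        enc.params["W"][5, 0] = 1.0  # embedding dim 0 reads patch element 5
        enc.params["b"][:] = 0.0
        enc.params["pos"][:] = 0.0
        seq = extract_patches(np.arange(48, dtype=float).reshape(4, 4, 3), 2)
        out = encode_patches(seq, enc)
        np.testing.assert_array_equal(out[:, 0], seq.patches[:, 5])


# ---------------------------------------------------------------- transformer

class TestTransformerBlock:
    def test_zeroed_weights_reduce_to_identity(self, rng):
        """With MHA and MLP outputs zeroed only the skip connections remain."""
        blk = TransformerBlock(8, 2, rng)
        for name in ("Wo", "bo"):
            blk.mha.params[name][:] = 0.0
        blk.fc2.params["W"][:] = 0.0
        blk.fc2.params["b"][:] = 0.0
        x = rng.standard_normal((5, 8))
        np.testing.assert_allclose(transformer_block(x, blk), x)

    def test_permutation_equivariance(self, rng):
        """Permuting patch rows (tokens) permutes the output identically."""
        blk = TransformerBlock(8, 2, rng)
        x = rng.standard_normal((7, 8))
        perm = rng.permutation(7)
        np.testing.assert_allclose(
            transformer_block(x[perm], blk), transformer_block(x, blk)[perm],
            rtol=1e-10, atol=1e-12,
        )

    def test_block_gradients(self, rng):
        def numerical_grad(f, x, eps=1e-6):
            g = np.zeros_like(x)
            it = np.nditer(x, flags=["multi_index"])
            while not it.finished:
                i = it.multi_index
                old = x[i]
                x[i] = old + eps
                fp = f()
                x[i] = old - eps
                fm = f()
                x[i] = old
                g[i] = (fp - fm) / (2 * eps)
                it.iternext()
            return g

        blk = TransformerBlock(4, 2, rng)
        x = rng.standard_normal((1, 3, 4))
        w = rng.standard_normal((1, 3, 4))
        blk.zero_grad()
        blk.forward(x)
        dx = blk.backward(w.copy())

        def loss():
            return float(np.sum(blk.forward(x) * w))

        np.testing.assert_allclose(dx, numerical_grad(loss, x), rtol=1e-4, atol=1e-6)

    def test_head_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="divide"):
            TransformerBlock(8, 3, rng)


# ---------------------------------------------------------------- config

class TestConfig:
    def test_derived_quantities(self):
        cfg = ViTDetectorConfig(image_size=64, patch_size=16, projection_dim=32)
        assert cfg.num_patches == 16
        assert cfg.patch_elements == 768
        assert cfg.transformer_units == (64, 32)

    def test_indivisible_image_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ViTDetectorConfig(image_size=224, patch_size=33)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="rmsprop")


# ---------------------------------------------------------------- inference

TINY = ViTDetectorConfig(
    image_size=32, patch_size=16, projection_dim=16, num_heads=2,
    transformer_layers=1, mlp_head_units=(32,),
    # dropout off so capacity and reproducibility checks see exact losses
    attention_dropout=0.0, mlp_dropout=0.0, representation_dropout=0.0,
)


class TestPredictBox:
    def test_forced_full_image_box(self, rng):
        model = ViTDetector(TINY, seed=0)
        final = model.head[-2]  # Dense before the sigmoid
        final.params["W"][:] = 0.0
        final.params["b"][:] = np.array([-50.0, -50.0, 50.0, 50.0])  # sigmoid -> (0,0,1,1)
        box = model.predict_box(np.zeros((32, 32, 3)))
        assert box.as_tuple() == pytest.approx((0, 0, 32, 32), abs=1e-6)

    def test_corner_ordering_enforced(self, rng):
        model = ViTDetector(TINY, seed=0)
        final = model.head[-2]
        final.params["W"][:] = 0.0
        # fractions (0.5, 0.5, 0.25, 0.75): x pair arrives unordered
        logit = lambda p: np.log(p / (1 - p))
        final.params["b"][:] = [logit(0.5), logit(0.5), logit(0.25), logit(0.75)]
        box = model.predict_box(np.zeros((32, 32, 3)))
        assert box.x_min <= box.x_max and box.y_min <= box.y_max
        assert box.as_tuple() == pytest.approx((8, 16, 16, 24), abs=1e-6)

    def test_wrong_input_size_rejected(self):
        model = ViTDetector(TINY, seed=0)
        with pytest.raises(ValueError, match="preprocess"):
            model.predict_box(np.zeros((64, 64, 3)))

    def test_functional_alias_type_checks(self):
        with pytest.raises(TypeError):
            predict_box(np.zeros((32, 32, 3)), model="not-a-model")


# ---------------------------------------------------------------- training

def _tiny_dataset(rng, n=4, size=32):
    out = []
    for _ in range(n):
        img = rng.random((size, size, 3))
        x0, y0 = rng.uniform(2, 10, 2)
        out.append((img, BoundingBox(x0, y0, x0 + 12, y0 + 14)))
    return out


class TestTraining:
    def test_single_sample_overfits(self, rng):
        """Enough epochs on one example drive the MSE loss below 1e-3."""
        ds = _tiny_dataset(rng, n=1)
        cfg = TrainConfig(epochs=150, batch_size=1, seed=0, lr_schedule="constant")
        _, history = train(ds, TINY, cfg)
        assert history[-1]["loss"] < 1e-3

    def test_fixed_seed_reproducible_history(self, rng):
        ds = _tiny_dataset(rng, n=4)
        cfg = TrainConfig(epochs=5, batch_size=2, seed=9)
        _, h1 = train(ds, TINY, cfg)
        _, h2 = train(ds, TINY, cfg)
        assert h1 == h2

    def test_loss_history_logged_per_epoch(self, rng):
        ds = _tiny_dataset(rng, n=4)
        cfg = TrainConfig(epochs=3, seed=0)
        _, history = train(ds, TINY, cfg)
        assert [h["epoch"] for h in history] == [0, 1, 2]
        assert all(h["lr"] <= cfg.learning_rate for h in history)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TINY, TrainConfig())

    def test_linear_decay_schedule(self, rng):
        ds = _tiny_dataset(rng, n=2)
        cfg = TrainConfig(epochs=4, seed=0, learning_rate=0.4, lr_schedule="linear_decay")
        _, history = train(ds, TINY, cfg)
        assert [h["lr"] for h in history] == pytest.approx([0.4, 0.3, 0.2, 0.1])


class TestFineTune:
    def test_zero_learning_rate_keeps_parameters(self, rng):
        ds = _tiny_dataset(rng, n=2)
        model, _ = train(ds, TINY, TrainConfig(epochs=2, seed=0))
        before = [lay.params[k].copy() for lay in model.layers for k in lay.params]
        # epsilon learning rate with zero momentum: parameter drift ~1e-12
        cfg = TrainConfig(optimizer="sgd_momentum", learning_rate=1e-12,
                          momentum=0.0, weight_decay=0.0, epochs=1, batch_size=8, seed=1)
        fine_tune(model, ds, cfg)
        after = [lay.params[k] for lay in model.layers for k in lay.params]
        for b, a in zip(before, after):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_adam_request_warned_but_honoured(self, rng):
        ds = _tiny_dataset(rng, n=2)
        model, _ = train(ds, TINY, TrainConfig(epochs=1, seed=0))
        with pytest.warns(UserWarning, match="sgd_momentum"):
            fine_tune(model, ds, TrainConfig(optimizer="adam", epochs=1, seed=1))

    def test_fine_tuning_does_not_degrade_fit(self, rng):
        ds = _tiny_dataset(rng, n=4)
        model, h_train = train(ds, TINY, TrainConfig(epochs=30, seed=0))
        cfg = TrainConfig(optimizer="sgd_momentum", learning_rate=1e-4,
                          batch_size=8, epochs=10, seed=1)
        _, h_ft = fine_tune(model, ds, cfg)
        assert h_ft[-1]["loss"] <= h_train[-1]["loss"] + 0.05


# ---------------------------------------------------------------- checkpoints

class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = ViTDetector(TINY, seed=3)
        img = rng.random((32, 32, 3))
        expected = model.predict_box(img)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path, expected_config=TINY)
        assert loaded.predict_box(img).as_tuple() == pytest.approx(expected.as_tuple())

    def test_config_mismatch_refused(self, tmp_path):
        model = ViTDetector(TINY, seed=0)
        path = tmp_path / "model.npz"
        save_model(model, path)
        with pytest.raises(ValueError, match="does not match"):
            load_model(path, expected_config=DESK_CONFIG)
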