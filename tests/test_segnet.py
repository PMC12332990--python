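import numpy as np
import pytest

from adrenalct.io import CTVolume
from adrenalct.nn import Adam
from adrenalct.segnet import (
    SegModel,
    TrainConfig,
    build_model,
    combined_loss,
    dice_loss,
    focal_loss,
    grad_wrt_logits,
    load_checkpoint,
    save_checkpoint,
    sliding_window_infer,
    softmax,
    train,
)


class TestBuildModel:
    def test_output_shape_and_softmax(self, rng):
        model = build_model((4, 8), n_classes=3, seed=0)
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (1, 3, 8, 8, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_parameter_count_monotone(self):
        small = build_model((8, 16, 32), seed=0).parameter_count()
        large = build_model((32, 64, 128), seed=0).parameter_count()
        assert small < large

    def test_default_channel_plan(self):
        model = build_model(seed=0)
        assert model.channel_plan == (32, 64, 128, 256, 512)

    def test_invalid_channel_plan(self):
        with pytest.raises(ValueError, match="increasing"):
            build_model((32, 16), seed=0)
        with pytest.raises(ValueError):
            build_model((32,), seed=0)

    def test_plain_variant_same_interface(self, rng):
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        res = build_model((4, 8), residual=True, seed=0).predict_proba(x)
        plain = build_model((4, 8), residual=False, seed=0).predict_proba(x)
        assert res.shape == plain.shape

    def test_gradient_check(self, rng):
        # finite-difference oracle over a sample of parameters
        model = SegModel((2, 4), n_classes=3, residual=True, seed=0)
        x = rng.random((1, 1, 4, 4, 4)).astype(np.float32)
        t = rng.integers(0, 3, (1, 4, 4, 4))
        probs = softmax(model.forward(x))
        _, dprobs = combined_loss(probs, t, return_grad=True)
        model.backward(grad_wrt_logits(probs, dprobs))
        checked = 0
        for name, params, grads in model.named_parameters():
            for key, arr in params.items():
                flat, gflat = arr.ravel(), grads[key].ravel()
                for i in rng.choice(flat.size, min(2, flat.size), replace=False):
                    eps, orig = 1e-3, flat[i]
                    flat[i] = orig + eps
                    lp = combined_loss(softmax(model.forward(x)), t)
                    flat[i] = orig - eps
                    lm = combined_loss(softmax(model.forward(x)), t)
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - gflat[i]) <= 2e-2 * (abs(num) + 1.0)
                    checked += 1
        assert checked > 30


class TestDiceLoss:
    def test_perfect_prediction(self):
        t = np.zeros((1, 4, 4, 4), dtype=int)
        t[0, :2] = 1
        probs = np.moveaxis(np.eye(3)[t], -1, 1)
        assert dice_loss(probs, t) < 1e-4

    def test_uniform_third_half_foreground(self):
        # closed form: per-class soft dice (2*(1/3)*(N/2)) / ((1/3)N + N/2)
        # = 0.4 -> loss 0.6
        t = np.zeros((1, 4, 4, 4), dtype=int)
        t[0, :2] = 1  # class 1 covers half the voxels; class 2 absent
        probs = np.full((1, 3, 4, 4, 4), 1.0 / 3.0)
        assert abs(dice_loss(probs, t) - 0.6) < 1e-6

    def test_empty_class_near_zero_loss(self):
        t = np.zeros((1, 4, 4, 4), dtype=int)  # no foreground at all
        probs = np.zeros((1, 3, 4, 4, 4))
        probs[:, 0] = 1.0
        assert dice_loss(probs, t) < 1e-3

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((1, 3, 4, 4, 4)), np.zeros((1, 5, 5, 5), dtype=int))

    def test_bounded(self, rng):
        for _ in range(10):
            logits = rng.normal(size=(1, 3, 4, 4, 4))
            t = rng.integers(0, 3, (1, 4, 4, 4))
            loss = dice_loss(softmax(logits), t)
            assert 0.0 <= loss <= 1.0


class TestFocalLoss:
    def test_gamma0_equals_cross_entropy(self, rng):
        logits = rng.normal(size=(1, 3, 4, 4, 4))
        probs = softmax(logits)
        t = rng.integers(0, 3, (1, 4, 4, 4))
        onehot = np.moveaxis(np.eye(3)[t], -1, 1)
        ce = float(-(onehot * np.log(probs)).sum() / t.size)
        assert abs(focal_loss(probs, t, gamma=0.0, alpha=1.0) - ce) < 1e-9

    def test_single_voxel_closed_form(self):
        # -0.25 * ln(0.5) for p_t = 0.5, gamma 2, alpha 1
        probs = np.zeros((1, 2, 1, 1, 1))
        probs[0, :, 0, 0, 0] = [0.5, 0.5]
        t = np.ones((1, 1, 1, 1), dtype=int)
        expected = -0.25 * np.log(0.5)
        assert abs(focal_loss(probs, t, gamma=2.0, alpha=1.0) - expected) < 1e-9

    def test_confident_correct_limit(self):
        t = np.zeros((1, 3, 3, 3), dtype=int)
        probs = np.zeros((1, 2, 3, 3, 3))
        probs[:, 0] = 1.0 - 1e-9
        probs[:, 1] = 1e-9
        assert focal_loss(probs, t) < 1e-6

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((1, 2, 2, 2, 2)), np.zeros((1, 2, 2, 2), dtype=int),
                       gamma=-1.0)


class TestTrainConfig:
    def test_lr_schedule_closed_form(self):
        cfg = TrainConfig(lr0=3e-4, decay_factor=0.9, decay_every=20)
        assert abs(cfg.lr_at(40) - 3e-4 * 0.9**2) < 1e-15
        assert cfg.lr_at(0) == 3e-4
        assert abs(cfg.lr_at(19) - 3e-4) < 1e-15
        assert abs(cfg.lr_at(20) - 2.7e-4) < 1e-15

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=0.0)
        with pytest.raises(ValueError):
            TrainConfig(decay_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(loss_weights=(0.0, 0.0))


class TestTraining:
    def _tiny_pair(self, rng):
        img = rng.random((16, 16, 8)).astype(np.float32) * 0.1
        msk = np.zeros((16, 16, 8), dtype=np.int16)
        msk[4:9, 4:9, 2:6] = 1
        msk[10:14, 10:14, 2:6] = 2
        img[msk == 1] += 0.5
        img[msk == 2] += 0.8
        from adrenalct.io import LabelMask

        return CTVolume(img), LabelMask(msk)

    def test_memorization_single_patch(self, rng):
        # overfit-one-patch check: loss drops below 0.2x initial in 100 steps
        x = rng.random((16, 16, 8)).astype(np.float32) * 0.1
        t = np.zeros((16, 16, 8), dtype=np.int16)
        t[1:8, 1:15, :] = 1
        t[9:15, 1:15, :] = 2
        x[t == 1] += 0.5
        x[t == 2] += 0.8
        model = build_model((4, 8, 16), seed=0)
        opt = Adam(model.named_parameters(), lr=1e-2)
        losses = []
        for _ in range(100):
            opt.zero_grad()
            probs = softmax(model.forward(x))
            loss, dprobs = combined_loss(probs, t, return_grad=True)
            model.backward(grad_wrt_logits(probs, dprobs))
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.2 * losses[0]

    def test_smoke_descent_and_determinism(self, rng):
        pairs = [self._tiny_pair(rng) for _ in range(3)]
        cfg = TrainConfig(
            lr0=1e-3, epochs=5, patches_per_epoch=4, patch_size=(16, 16, 8),
            noise_sigma_aug=0.0, rotation_range_deg=0.0, seed=0,
        )
        m1, h1 = train(build_model((4, 8), seed=1), pairs, pairs[:1], cfg)
        assert h1.train_loss[-1] < h1.train_loss[0]
        m2, h2 = train(build_model((4, 8), seed=1), pairs, pairs[:1], cfg)
        assert h1.train_loss == h2.train_loss
        # lr recorded per schedule; checkpoint flag only on improvement
        assert h1.lr == [cfg.lr_at(e) for e in h1.epochs]
        best = np.inf
        for saved, vloss in zip(h1.checkpoint_saved, h1.valid_loss):
            assert saved == (vloss < best)
            best = min(best, vloss)

    def test_empty_train_set(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model((4, 8), seed=0), [], [], TrainConfig())


class TestSlidingWindow:
    def _vol(self, shape, rng):
        return CTVolume(rng.random(shape).astype(np.float32))

    def test_single_tile_identity(self, rng):
        model = build_model((4, 8), seed=0)
        v = self._vol((16, 16, 8), rng)
        probs = sliding_window_infer(model, v, (16, 16, 8), overlap=0.25)
        direct = model.predict_proba(v.voxels)[0]
        np.testing.assert_allclose(probs, direct, atol=1e-6)

    def test_blended_probabilities_sum_to_one(self, rng):
        model = build_model((4, 8), seed=0)
        v = self._vol((24, 24, 12), rng)
        probs = sliding_window_infer(model, v, (16, 16, 8), overlap=0.5)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_tiling_arithmetic(self, rng):
        # a 16x16x32 volume with patch 16^3/8 and overlap 0 -> 2 z-tiles
        from adrenalct.segnet import _tile_starts

        assert _tile_starts(32, 16, 16) == [0, 16]
        assert _tile_starts(96, 96, 96) == [0]
        assert _tile_starts(192, 96, 96) == [0, 96]
        assert _tile_starts(100, 96, 72) == [0, 4]  # clamped final tile

    def test_smaller_than_patch_padded(self, rng):
        model = build_model((4, 8), seed=0)
        v = self._vol((10, 10, 6), rng)
        probs = sliding_window_infer(model, v, (16, 16, 8), overlap=0.0)
        assert probs.shape == (3, 10, 10, 6)

    def test_invalid_overlap(self, rng):
        model = build_model((4, 8), seed=0)
        with pytest.raises(ValueError):
            sliding_window_infer(model, self._vol((16, 16, 8), rng), (16, 16, 8), 0.95)


class TestCheckpoint:
    def test_roundtrip(self, rng, tmp_path):
        model = build_model((4, 8), seed=3)
        path = save_checkpoint(model, tmp_path / "ckpt.npz")
        loaded, _ = load_checkpoint(path)
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(
            loaded.predict_proba(x), model.predict_proba(x), atol=1e-7
        )
        assert loaded.channel_plan == model.channel_plan
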