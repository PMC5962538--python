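"""Preprocessing, Generalised Dice Loss, minibatching, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conefinder as cf
from conefinder.network import forward_batch, init_params
from conefinder.synthetic import make_sample
from conefinder.training import (TrainingConfig, cross_entropy_loss,
                                 generalised_dice_loss, preprocess,
                                 sample_minibatch, train)


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        assert np.allclose(preprocess(np.full((5, 5), 3.7)), 0, atol=1e-6)

    def test_two_value_image(self):
        out = preprocess(np.array([[0.0, 2.0]]))
        assert np.allclose(out, [[-1.0, 1.0]])

    def test_variance_unchanged(self, rng):
        img = rng.normal(2.0, 1.3, (30, 40))
        out = preprocess(img)
        assert abs(out.mean()) <= 1e-6
        assert out.std() == pytest.approx(img.std(), rel=1e-5)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.empty((0, 0)))


def _one_hot(cone):
    m = np.zeros(cone.shape + (2,))
    m[..., 1] = cone
    m[..., 0] = 1 - cone
    return m


class TestGeneralisedDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        truth = _one_hot((rng.random((6, 6)) < 0.3).astype(float))
        assert generalised_dice_loss(truth, truth) == pytest.approx(0.0)

    def test_complement_prediction_is_one(self, rng):
        truth = _one_hot((rng.random((6, 6)) < 0.3).astype(float))
        assert generalised_dice_loss(truth[..., ::-1], truth) == \
            pytest.approx(1.0)

    def test_hand_evaluated_2x2_case(self):
        """Truth one cone pixel of four, uniform 0.5 prediction -> 5/8."""
        truth = _one_hot(np.array([[1.0, 0.0], [0.0, 0.0]]))
        pred = np.full((2, 2, 2), 0.5)
        assert generalised_dice_loss(pred, truth) == pytest.approx(0.625)

    def test_absent_class_stays_finite(self):
        truth = _one_hot(np.zeros((4, 4)))      # background only
        pred = np.full((4, 4, 2), 0.5)
        loss = generalised_dice_loss(pred, truth)
        assert np.isfinite(loss) and 0 <= loss <= 1

    def test_batch_is_mean_of_images(self, rng):
        t1 = _one_hot((rng.random((5, 5)) < 0.4).astype(float))
        t2 = _one_hot((rng.random((5, 5)) < 0.4).astype(float))
        p1 = np.clip(rng.random((5, 5, 2)), 1e-3, 1)
        p1 /= p1.sum(-1, keepdims=True)
        p2 = np.clip(rng.random((5, 5, 2)), 1e-3, 1)
        p2 /= p2.sum(-1, keepdims=True)
        batch = generalised_dice_loss(np.stack([p1, p2]), np.stack([t1, t2]))
        singles = (generalised_dice_loss(p1, t1)
                   + generalised_dice_loss(p2, t2)) / 2
        assert batch == pytest.approx(singles)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_on_probabilistic_predictions(self, seed):
        r = np.random.default_rng(seed)
        truth = _one_hot((r.random((6, 6)) < r.uniform(0.05, 0.9)).astype(float))
        pred = r.random((6, 6, 2))
        pred /= pred.sum(-1, keepdims=True)
        loss = generalised_dice_loss(pred, truth)
        assert 0.0 <= loss <= 1.0

    def test_monotone_along_convex_path_to_truth(self, rng):
        truth = _one_hot((rng.random((8, 8)) < 0.3).astype(float))
        pred = rng.random((8, 8, 2))
        pred /= pred.sum(-1, keepdims=True)
        losses = [generalised_dice_loss((1 - t) * pred + t * truth, truth)
                  for t in np.linspace(0, 1, 6)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        truth = _one_hot((rng.random((4, 4)) < 0.3).astype(float))
        pred = rng.uniform(0.1, 0.9, (4, 4, 2))
        loss, grad = generalised_dice_loss(pred, truth, return_grad=True)
        eps = 1e-7
        flat = pred.reshape(-1)
        for i in rng.choice(flat.size, 8, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = generalised_dice_loss(pred, truth)
            flat[i] = orig - eps
            lm = generalised_dice_loss(pred, truth)
            flat[i] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(
                grad.reshape(-1)[i], rel=1e-4, abs=1e-9)


class TestSampleMinibatch:
    def test_batch_of_eight_full_size_crops(self, rng):
        imgs = [(rng.random((130, 131)).astype(np.float32),
                 _one_hot(np.zeros((130, 131))))]
        x, y = sample_minibatch(imgs, 128, 8, rng)
        assert x.shape == (8, 128, 128, 1)
        assert y.shape == (8, 128, 128, 2)
        assert np.abs(x.mean(axis=(1, 2, 3))).max() <= 1e-5  # crops centred

    def test_exact_size_image_yields_itself(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        x, _ = sample_minibatch([(img, _one_hot(np.zeros((32, 32))))],
                                32, 4, rng)
        for b in range(4):
            assert np.allclose(x[b, ..., 0], preprocess(img), atol=1e-6)

    def test_fixed_rng_reproduces_batch(self):
        imgs = [(np.random.default_rng(0).random((64, 64)).astype(np.float32),
                 _one_hot(np.zeros((64, 64))))]
        xa, ya = sample_minibatch(imgs, 32, 4, np.random.default_rng(9))
        xb, yb = sample_minibatch(imgs, 32, 4, np.random.default_rng(9))
        assert np.array_equal(xa, xb) and np.array_equal(ya, yb)

    def test_too_small_image_names_offender(self, rng):
        imgs = [(np.zeros((16, 16), np.float32), _one_hot(np.zeros((16, 16))))]
        with pytest.raises(ValueError, match="image 0"):
            sample_minibatch(imgs, 32, 2, rng)


def _tiny_sample(seed, size=48, noiseless=True):
    spec = cf.MosaicSpec(size, size, spacing=11, jitter=0.05, occupancy=1.0,
                         contrast=1.0,
                         noise_sigma=0.0 if noiseless else 0.05,
                         background_sigma=0.0 if noiseless else 0.08,
                         seed=seed)
    return make_sample(spec)


class TestTrainLoop:
    def test_loss_decreases_on_single_image(self):
        """Smoke test: five epochs on one noiseless mosaic reduce the loss."""
        s = _tiny_sample(0, size=32)
        cfg = TrainingConfig(batch_size=4, crop_size=32, epoch_size=2,
                             patience=10, max_epochs=5, seed=1)
        _, hist = train([s], [s], cfg, params=init_params(1, units=2, hidden=8))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_patience_honoured_exactly(self):
        """Training stops exactly `patience` epochs after the best epoch."""
        s = _tiny_sample(1, size=32)
        cfg = TrainingConfig(batch_size=2, crop_size=32, epoch_size=1,
                             patience=3, max_epochs=60, seed=2)
        _, hist = train([s], [s], cfg, params=init_params(2, units=2, hidden=8))
        if hist.stopped_epoch < 59:     # early stop triggered
            assert hist.stopped_epoch == hist.best_epoch + 3
        assert hist.best_epoch <= hist.stopped_epoch
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_identical_seeds_identical_histories(self):
        s = _tiny_sample(2, size=32, noiseless=False)
        cfg = TrainingConfig(batch_size=2, crop_size=32, epoch_size=2,
                             patience=5, max_epochs=3, seed=11)
        p1, h1 = train([s], [s], cfg, params=init_params(4, units=2, hidden=8))
        p2, h2 = train([s], [s], cfg, params=init_params(4, units=2, hidden=8))
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        for (na, xa), (_, xb) in zip(p1.arrays(), p2.arrays()):
            assert np.array_equal(xa, xb), na

    def test_overfits_small_noiseless_set(self):
        """Reaches train-set segmentation Dice >= 0.95 on 4 clean mosaics."""
        samples = [_tiny_sample(k) for k in range(4)]
        cfg = TrainingConfig(batch_size=4, crop_size=48, epoch_size=4,
                             patience=100, max_epochs=100, seed=5)
        _, hist = train(samples, samples, cfg,
                        params=init_params(5, units=6, hidden=16))
        assert max(hist.val_dice) >= 0.95

    def test_gdl_resists_class_imbalance_where_cross_entropy_collapses(self):
        """On a ~1%-cone fixture GDL keeps the cone class; plain CE does not."""
        samples = []
        for k in range(2):
            pts = np.array([[16.0 + 2 * k, 20.0], [34.0, 30.0 - 2 * k]])
            mask = cf.make_mask(pts, 2.0, (48, 48))
            img = cf.render_image(pts, cf.MosaicSpec(
                48, 48, spacing=14, jitter=0, occupancy=1, contrast=1.0,
                lobe_sigma=2.0, lobe_offset=3.5, noise_sigma=0.02,
                background_sigma=0.02, seed=k))
            samples.append((img, mask))
        assert samples[0][1][..., 1].mean() < 0.02

        def cone_pixels(loss_fn, max_epochs):
            cfg = TrainingConfig(batch_size=4, crop_size=48, epoch_size=6,
                                 patience=50, max_epochs=max_epochs, seed=3)
            params, _ = train(samples, samples, cfg,
                              params=init_params(3, units=4, hidden=16),
                              loss_fn=loss_fn)
            x = preprocess(samples[0][0])[None, ..., None]
            probs, _ = forward_batch(x, params)
            return int((probs[0][..., 1] >= 0.5).sum())

        assert cone_pixels(generalised_dice_loss, 25) > 0
        assert cone_pixels(cross_entropy_loss, 10) == 0

    def test_divergence_aborts_with_diagnostic(self):
        """A non-finite loss aborts training instead of continuing silently."""
        s = _tiny_sample(3, size=32)
        cfg = TrainingConfig(batch_size=2, crop_size=32, epoch_size=1,
                             patience=5, max_epochs=10, seed=0)
        bad = init_params(0, units=2, hidden=8)
        bad.fc2_w[0, 0] = np.inf        # poisons the logits -> NaN loss
        with np.errstate(invalid="ignore"):
            with pytest.raises(FloatingPointError, match="diverged"):
                train([s], [s], cfg, params=bad)
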