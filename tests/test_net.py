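"""Fusion algebra, Dice+focal loss, backprop correctness and training behavior."""

import numpy as np
import pytest

from panseg import net
from panseg.io_prep import PancreasVolume
from panseg.net import (NetConfig, UNet3D, dice_focal_loss,
                        fuse_probability_maps, one_hot, softmax_channels)


def _rand_probs(rng, shape):
    z = rng.normal(size=(3,) + shape)
    return softmax_channels(z)


class TestFusion:
    def test_uniform_prior_leaves_y_unchanged(self):
        rng = np.random.default_rng(0)
        Y = _rand_probs(rng, (4, 4, 4))
        X = np.full_like(Y, 1.0 / 3.0)
        np.testing.assert_allclose(fuse_probability_maps(Y, X), Y, atol=1e-12)

    def test_worked_product_example(self):
        Y = np.array([0.5, 0.3, 0.2]).reshape(3, 1, 1, 1)
        X = np.array([0.6, 0.3, 0.1]).reshape(3, 1, 1, 1)
        out = fuse_probability_maps(Y, X)[:, 0, 0, 0]
        np.testing.assert_allclose(out, [0.7317, 0.2195, 0.0488], atol=1e-4)

    def test_one_hot_absorbing(self):
        Y = np.array([1.0, 0.0, 0.0]).reshape(3, 1, 1, 1)
        X = np.array([0.2, 0.5, 0.3]).reshape(3, 1, 1, 1)
        np.testing.assert_allclose(fuse_probability_maps(Y, X)[:, 0, 0, 0],
                                   [1.0, 0.0, 0.0])

    def test_channel_sums_to_one_including_zero_product_fallback(self):
        rng = np.random.default_rng(1)
        Y = _rand_probs(rng, (3, 3, 3))
        X = _rand_probs(rng, (3, 3, 3))
        X[:, 0, 0, 0] = 0.0  # both-models-reject voxel
        Y[:, 0, 0, 0] = 0.0
        out = fuse_probability_maps(Y, X)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(out[:, 0, 0, 0], 1.0 / 3.0)

    def test_commutative(self):
        rng = np.random.default_rng(2)
        Y, X = _rand_probs(rng, (2, 2, 2)), _rand_probs(rng, (2, 2, 2))
        np.testing.assert_allclose(fuse_probability_maps(Y, X),
                                   fuse_probability_maps(X, Y), atol=1e-12)

    def test_associative_up_to_normalization(self):
        rng = np.random.default_rng(3)
        A, B, C = (_rand_probs(rng, (2, 2, 2)) for _ in range(3))
        left = fuse_probability_maps(fuse_probability_maps(A, B), C)
        right = fuse_probability_maps(A, fuse_probability_maps(B, C))
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fuse_probability_maps(np.zeros((3, 2, 2, 2)), np.zeros((3, 4, 4, 4)))


class TestLoss:
    def test_perfect_prediction_is_near_zero(self):
        target = np.zeros((2, 2, 2), np.uint8)
        target[0] = 1
        target[1, 0] = 2
        target[1, 1] = 3
        pred = one_hot(target)
        loss = dice_focal_loss(pred, target)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_matches_hand_computation(self):
        # 2x2x2 block: 4 head, 2 body, 2 tail voxels; pred = 1/3 everywhere
        target = np.zeros((2, 2, 2), np.uint8)
        target[0] = 1
        target[1, 0] = 2
        target[1, 1] = 3
        pred = np.full((3, 2, 2, 2), 1.0 / 3.0)
        n, counts = 8, np.array([4, 2, 2])
        eps = 1e-7
        dice = (2 * counts / 3 + eps) / (n / 3 + counts + eps)
        dice_term = np.mean(1 - dice)
        focal_term = (1 - 1 / 3) ** 2 * (-np.log(1 / 3))
        expected = dice_term + focal_term
        assert dice_focal_loss(pred, target) == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        target = rng.integers(1, 4, size=(3, 3, 3)).astype(np.uint8)
        pred = _rand_probs(rng, (3, 3, 3))
        base = dice_focal_loss(pred, target)
        perm = rng.permutation(27)
        pred_p = pred.reshape(3, -1)[:, perm].reshape(3, 3, 3, 3)
        target_p = target.reshape(-1)[perm].reshape(3, 3, 3)
        assert dice_focal_loss(pred_p, target_p) == pytest.approx(base, rel=1e-12)

    def test_loss_is_nonnegative_and_penalizes_wrong(self):
        target = np.ones((2, 2, 2), np.uint8)
        wrong = one_hot(np.full((2, 2, 2), 3, np.uint8))
        assert dice_focal_loss(wrong, target) > dice_focal_loss(one_hot(target),
                                                                target)

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        target = rng.integers(1, 4, size=(2, 2, 2)).astype(np.uint8)
        pred = _rand_probs(rng, (2, 2, 2))
        loss, grad = dice_focal_loss(pred, target, return_grad=True)
        h = 1e-6
        for _ in range(10):
            c = rng.integers(3)
            i, j, k = rng.integers(2, size=3)
            p2 = pred.copy()
            p2[c, i, j, k] += h
            num = (dice_focal_loss(p2, target) - loss) / h
            assert num == pytest.approx(grad[c, i, j, k], rel=1e-3, abs=1e-6)


class TestBackprop:
    def test_network_gradient_matches_finite_differences(self):
        cfg = NetConfig(depth=1, base_channels=2, use_bayes_input=False,
                        fuse=False, seed=0)
        model = UNet3D(cfg)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 4, 4, 4))
        target = rng.integers(1, 4, size=(4, 4, 4)).astype(np.uint8)
        mask = np.ones((4, 4, 4), bool)

        def compute_loss():
            logits, cache = model.forward(x)
            Y = softmax_channels(logits)
            loss, gY = dice_focal_loss(Y, target, mask=mask, return_grad=True)
            glogits = Y * (gY - (gY * Y).sum(axis=0, keepdims=True))
            grads, _ = model.backward(glogits, cache)
            return loss, grads

        loss0, grads = compute_loss()
        h = 1e-6
        for name in ("enc0_W", "bottleneck_W", "dec0_W", "head_W", "enc0_b"):
            p = model.params[name]
            idx = tuple(rng.integers(s) for s in p.shape)
            p[idx] += h
            loss1, _ = compute_loss()
            p[idx] -= h
            num = (loss1 - loss0) / h
            assert num == pytest.approx(grads[name][idx], rel=5e-3, abs=1e-7), name

    def test_forward_deterministic_with_frozen_weights(self):
        cfg = NetConfig.desk_test(seed=3)
        model = UNet3D(cfg)
        x = np.random.default_rng(0).normal(size=(cfg.in_channels, 8, 8, 8))
        np.testing.assert_array_equal(model.predict_probs(x),
                                      model.predict_probs(x))

    def test_save_load_round_trip(self, tmp_path):
        cfg = NetConfig.desk_test(seed=5)
        model = UNet3D(cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        back = UNet3D.load(path)
        assert back.config == cfg
        for k, v in model.params.items():
            np.testing.assert_array_equal(back.params[k], v)


def _toy_dataset(n=4, shape=(12, 8, 8), seed=0):
    """Tiny tube volumes with matching soft labels for training tests."""
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        mask = np.zeros(shape, bool)
        mask[1:-1, 3:6, 3:6] = True
        labels = np.zeros(shape, np.uint8)
        x = np.arange(shape[0])
        labels[(x < 5)[:, None, None] & mask] = 1
        labels[((x >= 5) & (x < 8))[:, None, None] & mask] = 2
        labels[(x >= 8)[:, None, None] & mask] = 3
        intens = np.where(mask, labels * 0.3 + rng.normal(0, 0.05, shape), 0.0)
        vol = PancreasVolume(np.clip(intens, 0, 1), mask)
        X = np.full((3,) + shape, 0.0)
        noisy = 0.7 * one_hot(labels) + 0.1
        X[:, mask] = noisy[:, mask] / noisy[:, mask].sum(axis=0)
        data.append((vol, labels, X))
    return data


class TestTraining:
    def test_loss_decreases_on_toy_dataset(self):
        data = _toy_dataset()
        cfg = NetConfig(depth=2, base_channels=4, max_epochs=8, lr=1e-3,
                        batch_size=2, seed=1)
        model, state = net.train(data, cfg)
        assert state.epochs_completed == 8
        assert state.losses[-1] < state.losses[0]
        assert 0 <= state.best_epoch < 8

    def test_same_seed_reproduces_loss_curve(self):
        data = _toy_dataset()
        cfg = NetConfig(depth=2, base_channels=4, max_epochs=4, lr=1e-3, seed=9)
        _, s1 = net.train(data, cfg)
        _, s2 = net.train(data, cfg)
        assert s1.losses == s2.losses
        assert s1.dsc_history == s2.dsc_history

    def test_uniform_bayes_map_equals_plain_network(self):
        # fusion with a uniform map is the identity, so training with it
        # must match the fusion-free path bit for bit
        data = _toy_dataset()
        uniform = [(v, l, np.where(np.broadcast_to(v.mask, (3,) + v.mask.shape), 1.0 / 3.0, 0.0))
                   for v, l, _ in data]
        cfg_fused = NetConfig(depth=1, base_channels=4, max_epochs=3, lr=1e-3,
                              use_bayes_input=False, fuse=True, seed=2)
        cfg_plain = NetConfig(depth=1, base_channels=4, max_epochs=3, lr=1e-3,
                              use_bayes_input=False, fuse=False, seed=2)
        m1, s1 = net.train(uniform, cfg_fused)
        m2, s2 = net.train([(v, l, None) for v, l, _ in data], cfg_plain)
        np.testing.assert_allclose(s1.losses, s2.losses, rtol=1e-9)
        for k in m1.params:
            np.testing.assert_allclose(m1.params[k], m2.params[k], atol=1e-7)

    def test_too_few_cases_rejected(self):
        data = _toy_dataset(n=1)
        with pytest.raises(ValueError, match="at least 2"):
            net.train(data, NetConfig.desk_test())


class TestPredict:
    def test_prediction_outside_mask_is_background(self):
        data = _toy_dataset(n=2)
        cfg = NetConfig(depth=1, base_channels=4, max_epochs=2, lr=1e-3, seed=0)
        model, _ = net.train(data, cfg)
        vol, labels, X = data[0]
        probs, pred = net.predict(model, vol, X)
        assert np.all(pred[~vol.mask] == 0)
        assert np.all(pred[vol.mask] > 0)
        assert np.all(probs[:, ~vol.mask] == 0)

    def test_one_hot_bayes_map_dominates_fusion(self):
        data = _toy_dataset(n=2)
        cfg = NetConfig(depth=1, base_channels=4, max_epochs=2, lr=1e-3, seed=0)
        model, _ = net.train(data, cfg)
        vol, labels, _ = data[0]
        X = one_hot(labels)
        _, pred = net.predict(model, vol, X)
        np.testing.assert_array_equal(pred[vol.mask], labels[vol.mask])

    def test_fusion_off_matches_plain_probability_path(self):
        data = _toy_dataset(n=2)
        cfg = NetConfig(depth=1, base_channels=4, max_epochs=2, lr=1e-3,
                        use_bayes_input=False, seed=0)
        model, _ = net.train([(v, l, np.where(np.broadcast_to(v.mask, (3,) + v.mask.shape), 1 / 3, 0.0))
                              for v, l, _ in data], cfg)
        vol, _, X = data[0]
        probs_off, _ = net.predict(model, vol, X, fuse=False)
        probs_none, _ = net.predict(model, vol, None, fuse=False)
        np.testing.assert_array_equal(probs_off, probs_none)
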