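"""Slice-wise U-Net: Dice metric, gradients, training behaviour, inference."""

import numpy as np
import pytest

from osteoseg._nn import UNet2D, bce_loss, soft_dice_loss
from osteoseg.io import ImageVolume, ProbabilityVolume
from osteoseg.model import (
    NetConfig,
    apply_threshold,
    build_model,
    dice_score,
    predict_volume,
    train,
)
from osteoseg.preprocess import SliceDataset


class TestDiceScore:
    def test_identical_masks_score_100(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3] = True
        assert dice_score(m, m) == 100.0

    def test_disjoint_masks_score_0(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_score(a, b) == 0.0

    def test_counted_example(self):
        # |S| = 6, |R| = 4, |S ∩ R| = 3  ->  2*3/(6+4) = 60%
        S = np.zeros(10, dtype=bool)
        R = np.zeros(10, dtype=bool)
        S[:6] = True
        R[3:7] = True
        assert dice_score(S, R) == pytest.approx(60.0)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice_score(z, z) == 100.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((6, 6)) > 0.5
            b = rng.random((6, 6)) > 0.5
            d = dice_score(a, b)
            assert d == dice_score(b, a)
            assert 0.0 <= d <= 100.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBuildModel:
    def test_biases_initialised_to_zero(self):
        net = build_model(NetConfig(depth=3, base_filters=8, seed=1))
        for layer in net.layers():
            assert np.all(layer.b == 0.0)

    def test_same_seed_identical_weights(self):
        n1 = build_model(NetConfig(depth=3, base_filters=8, seed=5))
        n2 = build_model(NetConfig(depth=3, base_filters=8, seed=5))
        for l1, l2 in zip(n1.layers(), n2.layers()):
            assert np.array_equal(l1.W, l2.W)

    def test_output_shape_and_range(self):
        net = build_model(NetConfig(depth=4, base_filters=4, seed=0))
        x = np.random.default_rng(0).random((2, 1, 128, 128))
        p = net.forward(x)
        assert p.shape == (2, 1, 128, 128)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_input_errors_with_padding_hint(self):
        net = build_model(NetConfig(depth=4, base_filters=4, seed=0))
        with pytest.raises(ValueError, match="pad"):
            net.forward(np.zeros((1, 1, 100, 100)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(depth=1)
        with pytest.raises(ValueError):
            NetConfig(threshold=1.5)


class TestGradients:
    @pytest.mark.parametrize("loss_fn", [soft_dice_loss, bce_loss])
    def test_backprop_matches_numerical_gradient(self, loss_fn):
        net = UNet2D(depth=2, base_filters=4, in_channels=1, seed=0)
        for layer in net.layers():
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((2, 1, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)

        def loss_of():
            return loss_fn(net.forward(x, remember=True), t)

        _, dp = loss_of()
        net.backward(dp)
        grads = [g.copy() for g in net.grads()]
        for p, g in zip(net.params(), grads):
            flat = p.reshape(-1)
            for k in range(0, flat.size, max(1, flat.size // 5)):
                eps, old = 1e-6, flat[k]
                flat[k] = old + eps
                l1, _ = loss_of()
                flat[k] = old - eps
                l2, _ = loss_of()
                flat[k] = old
                num = (l1 - l2) / (2 * eps)
                assert num == pytest.approx(g.reshape(-1)[k], rel=1e-4, abs=1e-9)


def tiny_dataset(masks_value, n=12, m=16):
    rng = np.random.default_rng(0)
    images = rng.uniform(0, 255, (n, m, m)).astype(np.float32)
    masks = np.full((n, m, m), masks_value, dtype=np.uint8)
    return SliceDataset(images=images, masks=masks, provenance=[("c", i) for i in range(n)])


class TestTraining:
    def test_all_empty_masks_converge_to_empty_predictions(self):
        ds = tiny_dataset(0)
        cfg = NetConfig(
            depth=2, base_filters=4, epochs=20, batch_size=4, seed=0,
            optimizer="adam", learning_rate=1e-3, loss="bce+dice",
        )
        net = build_model(cfg)
        records = train(net, ds, ds, cfg)
        # both-empty Dice convention: perfect agreement on empty targets
        assert records[-1].val_dice == pytest.approx(100.0, abs=1e-6)

    def test_empty_dataset_rejected(self):
        ds = SliceDataset(
            images=np.zeros((0, 16, 16)), masks=np.zeros((0, 16, 16), dtype=np.uint8),
            provenance=[],
        )
        with pytest.raises(ValueError):
            train(build_model(NetConfig(depth=2, base_filters=4)), ds, None,
                  NetConfig(depth=2, base_filters=4))

    def test_divergence_aborts_with_diagnostic(self):
        ds = tiny_dataset(1)
        cfg = NetConfig(
            depth=2, base_filters=4, epochs=5, batch_size=4, seed=0,
            optimizer="sgd", learning_rate=1e18, loss="bce",
        )
        net = build_model(cfg)
        with pytest.raises(RuntimeError, match="diverged"):
            train(net, ds, None, cfg)

    def test_smoke_benchmark_reaches_dice_090(self, smoke_run):
        assert smoke_run["records"][-1].val_dice >= 90.0

    def test_noise_degrades_accuracy_but_model_still_learns(self):
        # noise-free phantoms are nearly solvable; the hard noise setting
        # (2.5 sigma tissue contrast) degrades but must stay well-learnable
        from conftest import make_training_setup
        from osteoseg.phantom import NOISE_SD_HARD

        scores = {}
        for tag, noise, epochs in (("easy", 0.0, 10), ("hard", NOISE_SD_HARD, 12)):
            setup = make_training_setup(noise_sd=noise, n_cases=6, seed=11)
            cfg = NetConfig(
                depth=3, base_filters=8, epochs=epochs, batch_size=8, seed=0,
                optimizer="adam", learning_rate=1e-3, loss="bce+dice",
            )
            net = build_model(cfg)
            records = train(net, setup["train_ds"], setup["val_ds"], cfg)
            scores[tag] = records[-1].val_dice
        assert scores["easy"] >= 95.0
        assert scores["hard"] >= 85.0
        assert scores["hard"] < scores["easy"]

    def test_train_dice_trend_non_decreasing(self, smoke_run):
        dice = np.array([r.train_dice for r in smoke_run["records"]])
        window = 5
        smoothed = np.convolve(dice, np.ones(window) / window, mode="valid")
        assert np.all(np.diff(smoothed) > -1.0)  # monotone trend, small jitter allowed

    def test_inference_consistent_with_training_monitor(self, smoke_run):
        # volume-wise prediction at 0.5 must match the epoch-end val Dice
        net, cfg = smoke_run["net"], smoke_run["config"]
        scores = []
        for cid in smoke_run["val_ids"]:
            prob = predict_volume(net, smoke_run["normed"][cid], cfg)
            pred = apply_threshold(prob, 0.5)
            for k in range(pred.labels.shape[0]):
                scores.append(dice_score(pred.labels[k], smoke_run["masks"][cid].labels[k]))
        assert np.mean(scores) == pytest.approx(smoke_run["records"][-1].val_dice, abs=1.0)


class TestPredictVolume:
    def test_untrained_model_yields_valid_probabilities(self):
        cfg = NetConfig(depth=2, base_filters=4, seed=0)
        net = build_model(cfg)
        vol = ImageVolume(np.random.default_rng(0).uniform(0, 255, (4, 16, 16)))
        prob = predict_volume(net, vol, cfg)
        assert prob.shape == vol.shape
        assert prob.probs.min() >= 0.0 and prob.probs.max() <= 1.0

    def test_tri_axis_fusion_handles_non_square_slices(self):
        cfg = NetConfig(depth=2, base_filters=4, seed=0, fusion_mode="tri_axis_majority")
        net = build_model(cfg)
        vol = ImageVolume(np.random.default_rng(0).uniform(0, 255, (6, 16, 12)))
        prob = predict_volume(net, vol, cfg)
        assert prob.shape == (6, 16, 12)
        assert prob.probs.min() >= 0.0 and prob.probs.max() <= 1.0


class TestApplyThreshold:
    def test_masks_nested_over_tau_grid(self):
        rng = np.random.default_rng(1)
        prob = ProbabilityVolume(rng.random((4, 8, 8)))
        previous = None
        for tau in np.arange(0.1, 0.95, 0.1):
            mask = apply_threshold(prob, float(tau)).labels.astype(bool)
            if previous is not None:
                assert np.all(mask <= previous)  # raising tau only shrinks
            previous = mask

    def test_tiny_tau_on_positive_probs_gives_all_ones(self):
        prob = ProbabilityVolume(np.full((2, 4, 4), 0.01))
        assert apply_threshold(prob, 1e-6).labels.all()

    def test_tau_bounds(self):
        prob = ProbabilityVolume(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            apply_threshold(prob, 0.0)
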