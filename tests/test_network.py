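"""Segmentation network: structure, gradients, loss, training rules."""

import numpy as np
import pytest

from imlts.imgio import ImageVolume
from imlts.network import (
    Conv2D,
    DepthwiseConv2D,
    InstanceNorm,
    NetworkConfig,
    PlateauController,
    SegmentationNet,
    _dice_loss_grad,
    build_network,
    dice_coefficient,
    dice_loss,
    extract_patches,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    train,
)
from imlts.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(NetworkConfig.desk_scale(input_size=32, seed=0))


class TestStructure:
    def test_output_shape_and_range(self, tiny_net, rng):
        x = rng.normal(size=(2, 1, 64, 64))
        prob = tiny_net.forward(x)
        assert prob.shape == (2, 1, 64, 64)
        assert prob.min() > 0 and prob.max() < 1

    def test_forward_deterministic_given_weights(self, tiny_net, rng):
        x = rng.normal(size=(1, 1, 32, 32))
        assert np.array_equal(tiny_net.forward(x), tiny_net.forward(x))

    def test_parameter_count_is_desk_scale(self, tiny_net):
        assert tiny_net.n_parameters() < 2_000_000

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_size=255)

    def test_odd_spatial_input_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError, match="divisible"):
            tiny_net.forward(rng.normal(size=(1, 1, 30, 30)))


class TestGradients:
    """Analytic backprop against central finite differences."""

    def _check_layer(self, layer, x, rng, tol=1e-6):
        out = layer.forward(x)
        dout = rng.normal(size=out.shape)
        for _, g in layer.params():
            g[...] = 0.0
        dx = layer.backward(dout)
        eps = 1e-6
        for _ in range(5):
            i = tuple(rng.integers(0, s) for s in x.shape)
            x1, x2 = x.copy(), x.copy()
            x1[i] += eps
            x2[i] -= eps
            num = (np.sum(layer.forward(x1) * dout) - np.sum(layer.forward(x2) * dout)) / (2 * eps)
            assert abs(num - dx[i]) < tol

    def test_conv_stride1_and_2(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        for stride in (1, 2):
            self._check_layer(Conv2D(3, 4, 3, stride, rng), x, rng)

    def test_depthwise_stride1_and_2(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        for stride in (1, 2):
            self._check_layer(DepthwiseConv2D(3, 3, stride, rng), x, rng)

    def test_instance_norm(self, rng):
        layer = InstanceNorm(3)
        layer.g[:] = rng.normal(1.0, 0.2, 3)
        self._check_layer(layer, rng.normal(size=(2, 3, 6, 6)), rng)

    def test_dice_loss_gradient(self, rng):
        p = rng.random((3, 8, 8))
        t = (rng.random((3, 8, 8)) > 0.5).astype(float)
        g = _dice_loss_grad(p, t)
        eps = 1e-6
        for i in [(0, 2, 2), (1, 4, 4), (2, 7, 1)]:
            p1, p2 = p.copy(), p.copy()
            p1[i] += eps
            p2[i] -= eps
            num = (dice_loss(p1, t) - dice_loss(p2, t)) / (2 * eps)
            assert abs(num - g[i]) < 1e-8


class TestDiceLoss:
    def test_perfect_prediction(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1.0
        assert dice_loss(t, t) < 1e-6

    def test_disjoint_prediction(self):
        p = np.zeros((8, 8))
        p[:2] = 1.0
        t = np.zeros((8, 8))
        t[6:] = 1.0
        assert dice_loss(p, t) > 0.999

    def test_half_coverage_closed_form(self):
        t = np.zeros((1, 12))
        t[0, :4] = 1.0  # k=2 covered of 4 true
        p = np.zeros((1, 12))
        p[0, :2] = 1.0
        assert dice_loss(p, t) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_symmetric_for_binary_inputs(self, rng):
        a = (rng.random((6, 6)) > 0.5).astype(float)
        b = (rng.random((6, 6)) > 0.5).astype(float)
        assert dice_loss(a, b) == pytest.approx(dice_loss(b, a))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_out_of_range_prediction_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            dice_loss(np.full((4, 4), 1.5), np.ones((4, 4)))


class TestPlateauRule:
    def test_flat_sequence_drops_lr_exactly_once(self):
        ctrl = PlateauController(lr=0.1, factor=0.01, patience=4, early_stop_patience=10)
        ctrl.update(0.5)  # initial improvement
        for _ in range(4):
            ctrl.update(0.5)
        assert ctrl.lr == pytest.approx(0.1 * 0.01)
        ctrl.update(0.5)
        assert ctrl.lr == pytest.approx(0.1 * 0.01)  # not dropped again yet

    def test_early_stop_after_ten_stale_epochs(self):
        ctrl = PlateauController(lr=0.1, factor=0.01, patience=4, early_stop_patience=10)
        ctrl.update(0.5)
        stops = [ctrl.update(0.6)[1] for _ in range(10)]
        assert stops[:9] == [False] * 9 and stops[9] is True

    def test_improvement_resets_counters(self):
        ctrl = PlateauController(lr=0.1, factor=0.5, patience=2, early_stop_patience=4)
        ctrl.update(0.5)
        ctrl.update(0.6)
        improved, _ = ctrl.update(0.4)
        assert improved and ctrl.since_improvement == 0
        assert ctrl.lr == 0.1


@pytest.fixture(scope="module")
def small_run():
    splits = generate_dataset(8, PhantomSpec(noise_sigma=20.0), seed=5)
    xt, yt = extract_patches(splits["train"], 24, 64, seed=5)
    xv, yv = extract_patches(splits["val"], 8, 64, seed=6)
    cfg = NetworkConfig.desk_scale(max_epochs=2, seed=5)
    model = build_network(cfg)
    state = train(model, (xt, yt), (xv, yv), cfg)
    return model, state, splits


class TestTraining:
    def test_losses_bounded_and_recorded(self, small_run):
        _, state, _ = small_run
        assert state.epoch == 2
        assert all(0.0 <= l <= 1.0 for l in state.train_losses + state.val_losses)

    def test_learning_rate_never_increases(self, small_run):
        _, state, _ = small_run
        lrs = state.learning_rates
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_training_reproducible(self, small_run):
        _, state, splits = small_run
        xt, yt = extract_patches(splits["train"], 24, 64, seed=5)
        xv, yv = extract_patches(splits["val"], 8, 64, seed=6)
        cfg = NetworkConfig.desk_scale(max_epochs=2, seed=5)
        model2 = build_network(cfg)
        state2 = train(model2, (xt, yt), (xv, yv), cfg)
        assert np.allclose(state.train_losses, state2.train_losses, atol=1e-6)
        assert np.allclose(state.val_losses, state2.val_losses, atol=1e-6)

    def test_all_background_dataset_degrades_gracefully(self, rng):
        xs = rng.normal(size=(8, 1, 32, 32))
        ys = np.zeros((8, 32, 32), np.uint8)
        cfg = NetworkConfig.desk_scale(input_size=32, max_epochs=2, seed=0)
        model = build_network(cfg)
        state = train(model, (xs[:6], ys[:6]), (xs[6:], ys[6:]), cfg)
        assert all(np.isfinite(l) for l in state.train_losses)

    def test_empty_split_errors(self, tiny_net):
        with pytest.raises(ValueError, match="nonempty"):
            train(tiny_net, (np.zeros((0, 1, 32, 32)), np.zeros((0, 32, 32))),
                  (np.zeros((1, 1, 32, 32)), np.zeros((1, 32, 32))))

    def test_predict_mask_shape_spacing_and_threshold(self, small_run):
        model, _, splits = small_run
        vol = splits["test"][0].image
        mask = predict_mask(model, vol)
        assert mask.shape == vol.shape
        assert mask.spacing_mm == vol.spacing_mm
        empty = predict_mask(model, vol, threshold=1.0)
        assert empty.voxels.sum() == 0

    def test_untrained_model_refuses_prediction(self):
        model = build_network(NetworkConfig.desk_scale(seed=1))
        vol = ImageVolume(np.zeros((64, 64)), (1.0, 1.0))
        with pytest.raises(RuntimeError, match="train"):
            predict_mask(model, vol)

    def test_checkpoint_round_trip(self, small_run, tmp_path, rng):
        model, _, _ = small_run
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        x = rng.normal(size=(1, 1, 64, 64))
        assert np.array_equal(model.predict(x), back.predict(x))


def test_dice_coefficient_on_identical_and_empty_masks():
    a = np.zeros((8, 8))
    a[2:4, 2:4] = 1
    assert dice_coefficient(a, a) == pytest.approx(1.0, abs=1e-6)
    empty = np.zeros((8, 8))
    assert dice_coefficient(empty, empty) == pytest.approx(1.0)
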