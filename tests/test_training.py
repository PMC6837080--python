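"""Loss oracle, schedule, augmentation, and training-loop contracts."""

import math

import numpy as np
import pytest

from rowgraphics import nn
from rowgraphics.annotation import LabelMask
from rowgraphics.network import build_model
from rowgraphics.nn.tensor import Tensor
from rowgraphics.training import (
    AugSpec,
    TrainConfig,
    augment,
    lr_schedule,
    sample_aug_params,
    train,
    weighted_cross_entropy,
)


def loop_cross_entropy(scores, target, weights):
    """Independent per-pixel oracle: explicit softmax + weighted log-loss."""
    n, c, h, w = scores.shape
    total = 0.0
    for b in range(n):
        for i in range(h):
            for j in range(w):
                s = scores[b, :, i, j].astype(np.float64)
                p = np.exp(s - s.max())
                p /= p.sum()
                y = target[b, i, j]
                total += -weights[y] * math.log(p[y])
    return total / (n * h * w)


class TestWeightedCrossEntropy:
    def test_uniform_two_class_is_ln2(self):
        scores = Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        loss = weighted_cross_entropy(scores, np.zeros((1, 2, 2), dtype=int), [1.0, 1.0])
        assert float(loss.data) == pytest.approx(math.log(2), abs=1e-6)

    def test_perfect_prediction_loss_vanishes(self):
        scores = np.full((1, 2, 2, 2), -50.0, dtype=np.float32)
        target = np.array([[[0, 1], [1, 0]]])
        for i in range(2):
            for j in range(2):
                scores[0, target[0, i, j], i, j] = 50.0
        loss = weighted_cross_entropy(Tensor(scores), target, [0.5, 50.0])
        assert float(loss.data) < 1e-6

    def test_hand_set_2x2_with_weights(self):
        scores = np.array(
            [[[[2.0, -1.0], [0.5, 0.0]], [[-1.0, 3.0], [0.5, -2.0]]]], dtype=np.float32
        )
        target = np.array([[[0, 1], [1, 0]]])
        weights = np.array([0.5, 50.0])
        expected = loop_cross_entropy(scores, target, weights)
        loss = weighted_cross_entropy(Tensor(scores), target, weights)
        assert float(loss.data) == pytest.approx(expected, abs=1e-6)

    def test_matches_loop_oracle_random_8x8(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            scores = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
            target = rng.integers(0, 3, size=(1, 8, 8))
            weights = rng.uniform(0.1, 5.0, size=3)
            expected = loop_cross_entropy(scores, target, weights)
            loss = weighted_cross_entropy(Tensor(scores), target, weights)
            assert float(loss.data) == pytest.approx(expected, abs=1e-6)

    def test_out_of_range_class_rejected(self):
        scores = Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="class index"):
            weighted_cross_entropy(scores, np.full((1, 2, 2), 2), [1.0, 1.0])


class TestLrSchedule:
    def test_printed_settings(self):
        cfg = TrainConfig(base_lr=1e-4, lr_decay_factor=0.94, lr_decay_interval=10_000)
        assert lr_schedule(0, cfg) == pytest.approx(1e-4)
        assert lr_schedule(10_000, cfg) == pytest.approx(9.4e-5)
        assert lr_schedule(25_000, cfg) == pytest.approx(1e-4 * 0.94**2)

    def test_monotone_nonincreasing(self):
        cfg = TrainConfig(base_lr=1e-3, lr_decay_factor=0.9, lr_decay_interval=100)
        rates = [lr_schedule(s, cfg) for s in range(0, 2000, 37)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestAugment:
    def identity_spec(self, size):
        return AugSpec(
            scale_range=(1.0, 1.0),
            rotation_range=0.0,
            hflip_prob=0.0,
            brightness_delta=0.0,
            saturation_delta=0.0,
            crop_size=size,
        )

    def test_identity_configuration(self, rng):
        image = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
        mask = LabelMask(rng.integers(0, 2, size=(32, 32)).astype(np.uint8), {"background": 0, "line": 1})
        out_img, out_mask = augment(image, mask, self.identity_spec(32), rng)
        assert np.array_equal(out_img, image)
        assert np.array_equal(out_mask.values, mask.values)

    def test_label_closure_under_augmentation(self, rng):
        spec = AugSpec(scale_range=(0.5, 1.5), rotation_range=15, crop_size=48)
        image = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        values = np.zeros((64, 64), dtype=np.uint8)
        values[20:40, 30:35] = 1
        mask = LabelMask(values, {"background": 0, "line": 1})
        for _ in range(20):
            _, out_mask = augment(image, mask, spec, rng)
            assert set(np.unique(out_mask.values)) <= {0, 1}
            assert out_mask.values.shape == (48, 48)

    def test_deterministic_given_rng_seed(self):
        image = np.random.default_rng(0).integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        mask = LabelMask(np.zeros((64, 64), dtype=np.uint8), {"background": 0, "line": 1})
        spec = AugSpec(crop_size=48)
        a = augment(image, mask, spec, np.random.default_rng(77))
        b = augment(image, mask, spec, np.random.default_rng(77))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1].values, b[1].values)

    def test_small_image_padded_then_cropped(self, rng):
        spec = AugSpec(scale_range=(0.5, 0.5), rotation_range=0.0, hflip_prob=0.0,
                       brightness_delta=0.0, saturation_delta=0.0, crop_size=40)
        image = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        mask = LabelMask(np.ones((40, 40), dtype=np.uint8), {"background": 0, "line": 1})
        out_img, out_mask = augment(image, mask, spec, rng)
        assert out_img.shape == (40, 40, 3)
        assert out_mask.values.shape == (40, 40)
        assert (out_mask.values == 0).any()  # background fill visible

    def test_sampled_parameters_stay_in_ranges(self, rng):
        spec = AugSpec(scale_range=(0.5, 1.5), rotation_range=15.0)
        for _ in range(10_000):
            p = sample_aug_params(spec, rng)
            assert 0.5 <= p["scale"] <= 1.5
            assert -15.0 <= p["angle"] <= 15.0
            assert abs(p["brightness"]) <= 0.2 and abs(p["saturation"]) <= 0.2


def tiny_model():
    from rowgraphics.network import NetConfig

    return build_model(
        NetConfig(encoder_stages=((1, 4), (1, 8)), tail_blocks=1, tail_kernel=3,
                  multiscale_kernels=(3,), decoder_channels=8, n_classes=2),
        rng=0,
    )


def tiny_dataset(n=4, size=16, seed=0):
    rng = np.random.default_rng(seed)
    ds = []
    for _ in range(n):
        img = rng.integers(0, 255, size=(size, size, 3)).astype(np.uint8)
        values = np.zeros((size, size), dtype=np.uint8)
        values[:, size // 2 - 1 : size // 2 + 2] = 1
        ds.append((img, LabelMask(values, {"background": 0, "line": 1})))
    return ds


class TestTrainLoop:
    def test_history_structure_and_auto_weights(self):
        model = tiny_model()
        cfg = TrainConfig(batch_size=2, base_lr=1e-3, total_epochs=3, seed=0, class_weights="auto")
        _, history = train(model, tiny_dataset(), cfg)
        assert len(history) == 3
        assert {"epoch", "loss", "miou", "lr"} <= set(history[0])

    def test_seeded_runs_identical(self):
        cfg = TrainConfig(batch_size=2, base_lr=1e-3, total_epochs=3, seed=42)
        _, h1 = train(tiny_model(), tiny_dataset(), cfg)
        _, h2 = train(tiny_model(), tiny_dataset(), cfg)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_model(), [], TrainConfig(total_epochs=1))

    def test_nan_loss_aborts_with_diagnostic(self):
        class NaNModel(nn.Module):
            def __init__(self, inner):
                super().__init__()
                self.inner = inner
                self.config = inner.config

            def forward(self, x):
                out = self.inner(x)
                out.data[...] = np.nan
                return out

        model = NaNModel(tiny_model())
        with pytest.raises(FloatingPointError, match="lr="):
            train(model, tiny_dataset(), TrainConfig(batch_size=2, total_epochs=1))

    def test_total_iterations_cap(self):
        model = tiny_model()
        cfg = TrainConfig(batch_size=2, base_lr=1e-3, total_iterations=3, seed=0)
        _, history = train(model, tiny_dataset(n=4), cfg)
        # 2 steps/epoch -> stops during the second epoch
        assert len(history) == 2

    def test_checkpoint_written(self, tmp_path):
        path = tmp_path / "best.npz"
        cfg = TrainConfig(batch_size=2, base_lr=1e-3, total_epochs=2, seed=0,
                          checkpoint_path=str(path))
        train(tiny_model(), tiny_dataset(), cfg)
        assert path.exists()
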