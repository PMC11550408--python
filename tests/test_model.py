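"""Model construction, loss identities, stage blocking, and training behavior."""

import numpy as np
import pytest

from msanet import ConfigError, ModelConfig, MSANet, ValidationError, block_stages, compute_loss, train
from msanet.heatmaps import MultiScaleLabels, downsample_labels, make_label
from msanet.model import MultiScalePrediction, TrainConfig


class TestBuild:
    def test_stage_and_full_resolution_output_shapes(self, rng):
        model = MSANet(ModelConfig(rng_seed=0))
        image = rng.uniform(size=(64, 64, 3))
        pred = model.predict(image)
        assert pred.full_map.shape == (64, 64)
        assert {k: v.shape for k, v in pred.stage_maps.items()} == {
            4: (16, 16),
            8: (8, 8),
            16: (4, 4),
            32: (2, 2),
        }
        assert all(0 <= v.min() and v.max() <= 1 for v in pred.stage_maps.values())

    def test_single_enabled_stage(self, rng):
        cfg = ModelConfig(enabled_stages=frozenset({4}), rng_seed=0)
        pred = MSANet(cfg).predict(rng.uniform(size=(32, 32, 3)))
        assert set(pred.stage_maps) == {4}

    def test_same_seed_builds_identical_parameters(self):
        a = MSANet(ModelConfig(rng_seed=42))
        b = MSANet(ModelConfig(rng_seed=42))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_unknown_backbone_and_pretrained_rejected(self):
        with pytest.raises(ConfigError, match="backbone"):
            ModelConfig(backbone="convnext_imaginary")
        with pytest.raises(ConfigError, match="pretrained"):
            ModelConfig(pretrained=True)

    def test_indivisible_input_rejected(self, rng):
        with pytest.raises(ValidationError, match="pad"):
            MSANet(ModelConfig(rng_seed=0)).predict(rng.uniform(size=(30, 32, 3)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = MSANet(ModelConfig(rng_seed=5))
        image = rng.uniform(size=(32, 32, 3))
        before = model.predict(image).full_map
        model.save(tmp_path / "ckpt.npz")
        reloaded = MSANet.load(tmp_path / "ckpt.npz")
        assert np.array_equal(reloaded.predict(image).full_map, before)


class TestLoss:
    def test_exact_match_gives_zero_loss(self):
        maps = {1: np.random.default_rng(0).uniform(size=(8, 8)), 4: np.ones((2, 2)) * 0.5}
        pred = MultiScalePrediction(stage_maps={4: maps[4].copy()}, full_map=maps[1].copy())
        total, l_seg, l_ms = compute_loss(pred, MultiScaleLabels(maps=maps), 1.0)
        assert total == l_seg == l_ms == 0.0

    def test_full_resolution_term_by_hand(self):
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        p = np.array([[0.5, 0.0], [0.0, 0.0]])
        pred = MultiScalePrediction(stage_maps={}, full_map=p)
        total, l_seg, l_ms = compute_loss(pred, MultiScaleLabels(maps={1: gt}), 1.0)
        assert l_seg == pytest.approx(0.0625)
        assert l_ms == 0.0
        assert total == pytest.approx(0.0625)

    def test_total_with_one_stage_term_by_hand(self):
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        p = np.array([[0.5, 0.0], [0.0, 0.0]])
        pred = MultiScalePrediction(stage_maps={4: np.array([[0.8]])}, full_map=p)
        labels = MultiScaleLabels(maps={1: gt, 4: np.array([[1.0]])})
        total, l_seg, l_ms = compute_loss(pred, labels, 1.0)
        assert l_ms == pytest.approx(0.04)
        assert total == pytest.approx(0.1025)

    def test_lambda_weights_the_multiscale_term(self):
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = MultiScalePrediction(stage_maps={4: np.array([[0.8]])}, full_map=gt.copy())
        labels = MultiScaleLabels(maps={1: gt, 4: np.array([[1.0]])})
        total, _, _ = compute_loss(pred, labels, 0.5)
        assert total == pytest.approx(0.02)

    def test_shape_mismatch_names_the_scale(self):
        pred = MultiScalePrediction(stage_maps={4: np.zeros((2, 2))}, full_map=np.zeros((8, 8)))
        labels = MultiScaleLabels(maps={1: np.zeros((8, 8)), 4: np.zeros((3, 3))})
        with pytest.raises(ValidationError, match="1/4"):
            compute_loss(pred, labels, 1.0)


class TestBlocking:
    def test_block_deepest_stage(self):
        cfg = block_stages(ModelConfig(), {32})
        assert cfg.enabled_stages == frozenset({4, 8, 16})
        assert not cfg.raw_only

    def test_block_all_yields_raw_only_mode(self):
        cfg = block_stages(ModelConfig(), {4, 8, 16, 32})
        assert cfg.enabled_stages == frozenset()
        assert cfg.raw_only

    def test_blocking_is_idempotent(self):
        once = block_stages(ModelConfig(), {32, 16})
        twice = block_stages(once, {32, 16})
        assert once == twice

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValidationError):
            block_stages(ModelConfig(), {2})

    def test_raw_only_loss_is_segmentation_only(self, rng):
        cfg = block_stages(ModelConfig(rng_seed=0), {4, 8, 16, 32})
        pred = MSANet(cfg).predict(rng.uniform(size=(32, 32, 3)))
        assert pred.stage_maps == {}
        labels = MultiScaleLabels(maps={1: np.zeros((32, 32))})
        total, l_seg, l_ms = compute_loss(pred, labels, 1.0)
        assert total == l_seg
        assert l_ms == 0.0


class TestTraining:
    def _items(self, points, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        image = rng.uniform(0.0, 0.3, size=(*shape, 3))
        for x, y in points:
            image[int(y) - 2 : int(y) + 3, int(x) - 2 : int(x) + 3] = [0.8, 0.7, 0.45]
        label = make_label(points, shape, 3, 1.5)
        return [(image, downsample_labels(label.values))]

    def test_loss_history_length_equals_steps(self):
        model = MSANet(ModelConfig(rng_seed=1))
        history = train(model, self._items([(20.0, 30.0)]), TrainConfig(steps=5))
        assert len(history) == 5
        assert all(np.isfinite(history))

    def test_overfits_a_single_image(self):
        """Training on one image drives the loss down more than 20x, with the
        full-resolution term fit tightly; the coarse-stage terms keep a small
        capacity-limited floor."""
        model = MSANet(ModelConfig(rng_seed=1))
        items = self._items([(20.0, 30.0), (45.0, 15.0)])
        history = train(model, items, TrainConfig(steps=500, lr=3e-3, shuffle_seed=1))
        assert history[-1] < 0.05
        assert history[-1] < history[0] / 20
        _, l_seg, _ = compute_loss(model.predict(items[0][0]), items[0][1], 1.0)
        assert l_seg < 0.02

    def test_empty_image_converges_to_zero_map(self):
        model = MSANet(ModelConfig(rng_seed=2))
        items = self._items([])
        train(model, items, TrainConfig(steps=200, lr=3e-3, shuffle_seed=2))
        pred = model.predict(items[0][0])
        assert pred.full_map.mean() < 0.05

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            train(MSANet(ModelConfig(rng_seed=0)), [], TrainConfig(steps=1))

    def test_training_is_deterministic(self):
        items = self._items([(20.0, 30.0)])
        runs = []
        for _ in range(2):
            model = MSANet(ModelConfig(rng_seed=7))
            runs.append(train(model, items, TrainConfig(steps=10, shuffle_seed=7)))
        assert runs[0] == runs[1]
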