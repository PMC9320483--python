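import numpy as np
import pandas as pd
import pytest
from skinseg.model import (
    AugmentConfig,
    ModelState,
    NetworkConfig,
    TrainingConfig,
    augment,
    build_network,
    focal_loss,
    iou,
    make_targets,
    predict_tile,
    split_by_slide,
)


class TestNetworkShapes:
    def test_small_preset_256_shapes(self):
        cfg = NetworkConfig(input_side=256, preset="small", seed=0)
        net = build_network(cfg)
        x = np.zeros((1, 3, 256, 256), dtype=np.float32)
        a = x
        for lvl in net.levels:
            a = lvl.forward(a, train=False)
        assert a.shape[-2:] == (8, 8)  # 256 / 32 bottleneck
        y = net.forward(x, train=False)
        assert y.shape == (1, 2, 32, 32)  # 256 / 8

    def test_input_not_divisible_by_32_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_side=100, preset="small")

    def test_output_bounded_by_sigmoid(self):
        net = build_network(NetworkConfig(input_side=64, preset="small", seed=1))
        p = net.predict_proba(np.random.default_rng(0)
                              .normal(size=(2, 3, 64, 64)).astype(np.float32))
        assert p.min() >= 0.0 and p.max() <= 1.0

    @pytest.mark.parametrize("side", [64, 128, 224])
    def test_stride_contract_any_side(self, side):
        net = build_network(NetworkConfig(input_side=side, preset="small", seed=0))
        y = net.forward(np.zeros((1, 3, side, side), dtype=np.float32), train=False)
        assert y.shape[-1] == side // 8


class TestFocalLoss:
    def test_perfect_prediction_near_zero(self):
        t = (np.random.default_rng(0).random((4, 8, 8)) > 0.5).astype(np.float32)
        assert focal_loss(t, t, gamma=2.0) < 1e-5

    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, size=(2, 16, 16))
        t = (rng.random((2, 16, 16)) > 0.5).astype(np.float64)
        bce = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert focal_loss(p, t, gamma=0.0) == pytest.approx(bce, abs=1e-6)

    def test_hand_computed_single_pixel(self):
        # target 1, p=0.5, gamma=2: (1-0.5)^2 * ln 2 = 0.25 ln 2
        val = focal_loss(np.array([[0.5]]), np.array([[1.0]]), gamma=2.0)
        assert val == pytest.approx(0.25 * np.log(2), rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 2)), np.zeros((3, 3)), gamma=2.0)

    def test_value_matches_logit_gradient_path(self):
        from skinseg import nn

        rng = np.random.default_rng(2)
        z = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        t = (rng.random(z.shape) > 0.5).astype(np.float32)
        loss_z, _ = nn.focal_loss_grad_logits(z, t, 2.0)
        assert loss_z == pytest.approx(focal_loss(nn.sigmoid(z), t, 2.0), rel=1e-5)


class TestIoU:
    def test_identical_masks(self):
        m = np.eye(8, dtype=bool)
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0, 0] = True
        b[7, 7] = True
        assert iou(a, b) == 0.0

    def test_half_overlap_is_one_third(self):
        a = np.zeros(20, dtype=bool)
        b = np.zeros(20, dtype=bool)
        a[0:10] = True
        b[5:15] = True
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4), dtype=bool)
        assert iou(z, z) == 1.0


class TestAugment:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        tile = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 10:30] = 1
        return tile, mask

    def test_all_disabled_is_identity(self):
        tile, mask = self._pair()
        t, m = augment(tile, mask, seed=5, cfg=AugmentConfig.disabled())
        assert np.array_equal(t, tile) and np.array_equal(m, mask)

    def test_rotation_preserves_mask_count(self):
        tile, mask = self._pair(1)
        cfg = AugmentConfig(rotate90=True, flip=True, elastic=False, noise=False,
                            blur=False, brightness_contrast=False, color=False)
        for seed in range(8):
            _, m = augment(tile, mask, seed=seed, cfg=cfg)
            assert m.sum() == mask.sum()

    def test_small_elastic_changes_area_under_5pct(self):
        tile, mask = self._pair(2)
        cfg = AugmentConfig(rotate90=False, flip=False, elastic=True,
                            elastic_alpha=3.0, elastic_sigma=8.0, noise=False,
                            blur=False, brightness_contrast=False, color=False)
        _, m = augment(tile, mask, seed=3, cfg=cfg)
        assert abs(int(m.sum()) - int(mask.sum())) / mask.sum() < 0.05

    def test_seeded_determinism(self):
        tile, mask = self._pair(3)
        a = augment(tile, mask, seed=11)
        b = augment(tile, mask, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSplitBySlide:
    def _manifest(self, n_slides, rows_per_slide=4):
        return pd.DataFrame({
            "slide_path": [f"s{i}.png" for i in range(n_slides)
                           for _ in range(rows_per_slide)]})

    def test_ten_equal_slides_split_8_2(self):
        tr, va = split_by_slide(self._manifest(10), fraction=0.8, seed=0)
        assert tr["slide_path"].nunique() == 8
        assert va["slide_path"].nunique() == 2

    def test_no_slide_in_both_parts(self):
        tr, va = split_by_slide(self._manifest(7), fraction=0.7, seed=3)
        assert not set(tr["slide_path"]) & set(va["slide_path"])

    def test_same_seed_same_split(self):
        m = self._manifest(9)
        a = split_by_slide(m, 0.8, seed=5)
        b = split_by_slide(m, 0.8, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_single_slide_rejected(self):
        with pytest.raises(ValueError):
            split_by_slide(self._manifest(1), 0.8, seed=0)


class TestTraining:
    def test_history_and_best_state(self, trained_state):
        state, hist = trained_state
        assert len(hist.val_iou) == 10
        assert all(0.0 <= v <= 1.0 for v in hist.val_iou)
        # epoch-averaged loss trends down on separable data
        assert np.mean(hist.epoch_loss[-2:]) < np.mean(hist.epoch_loss[:2])

    def test_validation_iou_reaches_06_majority_of_seeds(self, quick_dataset,
                                                         trained_state):
        from skinseg.model import train

        # three seeds total: the session fixture (seed 0) plus two more
        passed = int(max(trained_state[1].val_iou) >= 0.6)
        for seed in (1, 2):
            net = build_network(NetworkConfig(input_side=256, preset="small",
                                              seed=seed))
            _, hist = train(quick_dataset, net,
                            TrainingConfig(learning_rate=1e-3, epochs=10,
                                           batch_size=8, seed=seed))
            passed += max(hist.val_iou) >= 0.6
        assert passed >= 2

    def test_config_round_trips(self):
        cfg = TrainingConfig(gamma=2.0, learning_rate=1e-4, seed=7)
        assert TrainingConfig.from_dict(cfg.to_dict()) == cfg

    def test_empty_dataset_rejected(self):
        from skinseg.model import TileDataset, train

        ds = TileDataset(tiles=np.zeros((0, 64, 64, 3), dtype=np.uint8),
                         labels=np.zeros((0, 64, 64), dtype=np.uint8),
                         slide_ids=np.array([], dtype=object))
        with pytest.raises(ValueError):
            train(ds, build_network(NetworkConfig(input_side=64, preset="small")),
                  TrainingConfig())


class TestPredictTile:
    def test_output_side_is_input_over_8(self, trained_state):
        state, _ = trained_state
        tile = np.full((256, 256, 3), 255, dtype=np.uint8)
        hm = predict_tile(state, tile)
        assert hm.probs.shape == (2, 32, 32)

    def test_background_tile_low_probability(self, trained_state):
        state, _ = trained_state
        rng = np.random.default_rng(0)
        tile = np.clip(rng.normal(246, 2, size=(256, 256, 3)), 0, 255).astype(np.uint8)
        hm = predict_tile(state, tile)
        assert hm.probs.mean(axis=(1, 2)).max() < 0.1

    def test_wrong_tile_size_rejected(self, trained_state):
        state, _ = trained_state
        with pytest.raises(ValueError):
            predict_tile(state, np.zeros((128, 128, 3), dtype=np.uint8))

    def test_inference_deterministic(self, trained_state):
        state, _ = trained_state
        rng = np.random.default_rng(1)
        tile = rng.integers(0, 255, size=(256, 256, 3), dtype=np.uint8)
        net = state.make_network()
        a = predict_tile(net, tile).probs
        b = predict_tile(net, tile).probs
        assert np.array_equal(a, b)


def test_model_state_round_trip(tmp_path, trained_state):
    state, _ = trained_state
    state.save(tmp_path / "model")
    back = ModelState.load(tmp_path / "model")
    assert back.config == state.config
    assert all(np.array_equal(a, b) for a, b in zip(back.weights, state.weights))


def test_make_targets_block_any():
    lab = np.zeros((16, 16), dtype=np.uint8)
    lab[0, 0] = 1   # single BD pixel -> its 8x8 block is positive
    lab[8:16, 8:16] = 2
    t = make_targets(lab, stride=8)
    assert t.shape == (2, 2, 2)
    assert t[0, 0, 0] == 1 and t[0].sum() == 1
    assert t[1, 1, 1] == 1 and t[1].sum() == 1
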