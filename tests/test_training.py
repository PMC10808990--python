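import numpy as np
import pytest

from fruitdet.geometry import BoundingBox, ImageAnnotation
from fruitdet.heatmap import ConfigurationError, allocate_samples, heatmap_branch_loss
from fruitdet.model import ModelConfig
from fruitdet.nn.autograd import Tensor
from fruitdet.synthetic import SceneConfig, generate_split
from fruitdet.training import (
    LayerTargets,
    TrainConfig,
    _heat_loss_tensor,
    build_layer_targets,
    is_small_object,
    total_loss,
    train,
)

from conftest import random_annotation


def box_wh(x, y, w, h):
    return BoundingBox(x, y, x + w, y + h)


class TestSmallObjectCriterion:
    @pytest.mark.parametrize(
        "w, h, img, expected",
        [
            (20, 20, (640, 640), True),     # 400 < 1024
            (100, 100, (640, 640), False),  # both clauses fail
            (40, 40, (2000, 2000), True),   # sqrt(1600/4e6) = 0.02 < 0.03
            (32, 32, (640, 640), False),    # boundary: area == 1024, rel 0.05
        ],
    )
    def test_rule(self, w, h, img, expected):
        assert is_small_object(box_wh(0, 0, w, h), *img) is expected

    def test_zero_area_image_rejected(self):
        with pytest.raises(ValueError):
            is_small_object(box_wh(0, 0, 5, 5), 0, 100)


class TestLayerRouting:
    def test_one_small_one_large(self):
        ann = ImageAnnotation(
            "a", 640, 640, [box_wh(10, 10, 20, 20), box_wh(100, 100, 200, 200)]
        )
        t = build_layer_targets(ann)
        assert t.routing == [1, 2]
        assert (t.heat[1] == 1).sum() == 1
        assert (t.heat[2] == 1).sum() == 1

    def test_all_large_scene_empties_layer_one(self):
        ann = ImageAnnotation("a", 640, 640, [box_wh(50, 50, 300, 300)])
        t = build_layer_targets(ann)
        assert not t.heat[1].any()

    def test_routing_conservation_on_random_scenes(self, rng):
        for i in range(100):
            ann = random_annotation(rng, 256, 256, max_boxes=8, min_size=6,
                                    max_size=120, image_id=f"i{i}")
            t = build_layer_targets(ann)
            assert len(t.routing) == len(ann.boxes)
            n1 = t.routing.count(1)
            n2 = t.routing.count(2)
            assert n1 + n2 == len(ann.boxes)

    def test_single_layer_takes_everything(self):
        ann = ImageAnnotation(
            "a", 640, 640, [box_wh(10, 10, 20, 20), box_wh(100, 100, 300, 300)]
        )
        t = build_layer_targets(ann, layer_factors={2: 4})
        assert t.routing == [2, 2]

    def test_size_and_offset_targets_at_center(self):
        box = box_wh(100, 100, 202, 100)  # center (201, 150), r=4 cell (50, 37)
        ann = ImageAnnotation("a", 640, 640, [box])
        t = build_layer_targets(ann)
        assert t.center_mask[2][37, 50]
        np.testing.assert_allclose(t.size[2][:, 37, 50], [202, 100])
        np.testing.assert_allclose(t.offset[2][:, 37, 50], [0.25, 0.5])


class TestTotalLoss:
    @staticmethod
    def _ideal_outputs(targets):
        out = {}
        for layer in targets.heat:
            out[layer] = {
                "heat": Tensor(targets.heat[layer][None, None]),
                "size": Tensor(targets.size[layer][None]),
                "offset": Tensor(targets.offset[layer][None]),
            }
        return out

    def test_ideal_outputs_zero_loss(self):
        ann = ImageAnnotation("a", 128, 128, [box_wh(20, 20, 60, 70)])
        t = build_layer_targets(ann)
        cfg = TrainConfig(epochs=1, lr_drop_epoch=1)
        loss, breakdown = total_loss(self._ideal_outputs(t), [t], cfg)
        assert breakdown["total"] < 1e-6

    def test_zero_weights_leave_heat_term(self, rng):
        ann = ImageAnnotation("a", 128, 128, [box_wh(20, 20, 60, 70)])
        t = build_layer_targets(ann)
        out = self._ideal_outputs(t)
        for layer in out:
            out[layer]["heat"] = Tensor(
                rng.uniform(0.1, 0.9, out[layer]["heat"].shape)
            )
        cfg = TrainConfig(epochs=1, lr_drop_epoch=1, lambda_size=0.0, lambda_off=0.0)
        loss, breakdown = total_loss(out, [t], cfg)
        assert breakdown["total"] == pytest.approx(breakdown["heat"], rel=1e-6)

    def test_heat_term_matches_numpy_reference(self, rng):
        """Autograd loss path equals the reference per-pixel formulation."""
        ann = ImageAnnotation("a", 128, 128, [box_wh(30, 30, 80, 60)])
        t = build_layer_targets(ann)
        H = t.heat[2]
        pred = rng.uniform(0.05, 0.95, H.shape)
        for strategy, choice in (("expanded", "continuous"),
                                 ("original", "focal"),
                                 ("original", "continuous")):
            cfg = TrainConfig(epochs=1, lr_drop_epoch=1,
                              allocation_strategy=strategy, loss_choice=choice)
            got = float(
                _heat_loss_tensor(
                    Tensor(pred[None, None]), H[None, None], strategy, choice, cfg.loss
                ).data
            )
            want = heatmap_branch_loss(pred, H, strategy, choice, cfg.loss)
            assert got == pytest.approx(want, abs=1e-5)

    def test_random_outputs_match_enumeration(self, rng):
        ann = ImageAnnotation("a", 64, 64, [box_wh(8, 8, 20, 24)])
        t = build_layer_targets(ann)
        out = {}
        for layer in t.heat:
            out[layer] = {
                "heat": Tensor(rng.uniform(0.1, 0.9, (1, 1) + t.heat[layer].shape)),
                "size": Tensor(rng.normal(10, 3, (1, 2) + t.heat[layer].shape)),
                "offset": Tensor(rng.uniform(0, 1, (1, 2) + t.heat[layer].shape)),
            }
        cfg = TrainConfig(epochs=1, lr_drop_epoch=1)
        loss, _ = total_loss(out, [t], cfg)
        # brute-force: per-pixel continuous loss + masked L1 means
        expected = 0.0
        for layer in t.heat:
            H = t.heat[layer]
            P = out[layer]["heat"].data[0, 0].astype(np.float64)
            expected += cfg.lambda_heat * heatmap_branch_loss(
                P, H, "expanded", "continuous", cfg.loss
            )
            m = t.center_mask[layer]
            count = max(1, m.sum())
            for arr, gt in ((out[layer]["size"].data[0], t.size[layer]),
                            (out[layer]["offset"].data[0], t.offset[layer])):
                l1 = np.abs(arr.astype(np.float64) - gt)[:, m].sum() / count
                expected += (cfg.lambda_size if gt is t.size[layer] else cfg.lambda_off) * l1
        assert float(loss.data) == pytest.approx(expected, rel=1e-4)

    def test_expanded_strategy_supervises_more_pixels(self):
        ann = ImageAnnotation("a", 256, 256, [box_wh(40, 40, 120, 140)])
        t = build_layer_targets(ann)
        H = t.heat[2]
        n_exp = allocate_samples(H, "expanded").positive_mask.sum()
        n_orig = allocate_samples(H, "original").positive_mask.sum()
        assert n_exp > n_orig == 1


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = SceneConfig(width=64, height=64, fruits_min=2, fruits_max=4,
                      occlusion_prob=0.0)
    return [
        (im, ann) for im, ann in generate_split(cfg, 12, seed=3, split_index=0)
    ]


def tiny_train_config(**over):
    base = dict(
        epochs=2, lr_drop_epoch=2, initial_lr=2e-3, batch_size=4, seed=1,
        eval_every=0,
    )
    base.update(over)
    return TrainConfig(**base)


class TestTrainLoop:
    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(lr_drop_epoch=200, epochs=100)
        with pytest.raises(ConfigurationError):
            TrainConfig(allocation_strategy="expanded", loss_choice="focal")
        with pytest.raises(ConfigurationError):
            TrainConfig(batch_size=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            train([], tiny_train_config())

    def test_lr_schedule_recorded(self, tiny_dataset):
        cfg = tiny_train_config(epochs=2, lr_drop_epoch=2, initial_lr=1e-3)
        result = train(tiny_dataset[:4], cfg)
        lrs = [rec["lr"] for rec in result.history]
        assert lrs == [1e-3, 1e-4]

    def test_full_schedule_drop_at_epoch_90(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(89) == 0.000125
        assert cfg.lr_at_epoch(90) == 0.000125 / 10

    def test_fixed_seed_reproduces_epoch_one_loss(self, tiny_dataset):
        cfg = tiny_train_config(epochs=1, lr_drop_epoch=1)
        a = train(tiny_dataset[:8], cfg)
        b = train(tiny_dataset[:8], cfg)
        assert a.history[0]["total"] == b.history[0]["total"]  # bit-for-bit

    def test_loss_trend_decreases(self, tiny_dataset):
        cfg = tiny_train_config(epochs=5, lr_drop_epoch=5)
        result = train(tiny_dataset, cfg)
        losses = [rec["total"] for rec in result.history]
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_metrics_log_written(self, tiny_dataset, tmp_path):
        cfg = tiny_train_config(epochs=1, lr_drop_epoch=1)
        train(tiny_dataset[:4], cfg, out_dir=tmp_path)
        assert (tmp_path / "metrics.jsonl").exists()
        assert (tmp_path / "checkpoint_final.npz").exists()

    def test_indivisible_image_size_rejected(self):
        ann = ImageAnnotation("a", 60, 60, [box_wh(10, 10, 20, 20)])
        im = np.zeros((60, 60, 3), dtype=np.uint8)
        with pytest.raises(ConfigurationError, match="multiple"):
            train([(im, ann)], tiny_train_config())

    def test_original_single_variant_trains(self, tiny_dataset):
        cfg = tiny_train_config(
            neck_variant="original_single", allocation_strategy="original",
            loss_choice="focal", epochs=1, lr_drop_epoch=1,
        )
        result = train(tiny_dataset[:4], cfg)
        assert result.model.layer_factors == {2: 4}
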