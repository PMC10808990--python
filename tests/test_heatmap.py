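import math

import numpy as np
import pytest

from fruitdet.geometry import BoundingBox, ImageAnnotation, iou
from fruitdet.heatmap import (
    ConfigurationError,
    GaussianEncodingConfig,
    LossConfig,
    allocate_samples,
    continuous_label_loss,
    encode_heatmap,
    gaussian_radius,
    heatmap_branch_loss,
    modified_focal_loss,
)


def brute_force_gaussian(shape, centers_radii, zero_threshold):
    """Direct per-pixel enumeration of the max-combined Gaussian code."""
    H = np.zeros(shape)
    for (cy, cx), radius in centers_radii:
        sigma = radius / 3.0 if radius > 0 else None
        for y in range(shape[0]):
            for x in range(shape[1]):
                if sigma is None:
                    v = 1.0 if (y, x) == (cy, cx) else 0.0
                elif abs(y - cy) <= int(radius) and abs(x - cx) <= int(radius):
                    v = math.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
                else:
                    v = 0.0
                H[y, x] = max(H[y, x], v)
    H[H < zero_threshold] = 0.0
    return H


class TestGaussianRadius:
    def test_degenerate_box(self):
        assert gaussian_radius(0, 10) == 0.0
        assert gaussian_radius(10, 0) == 0.0

    def test_monotone_in_size(self):
        assert gaussian_radius(64, 64) >= gaussian_radius(32, 32)

    def test_radius_maximal_under_diagonal_shift(self):
        """Brute-force IoU scan: shift by r keeps IoU >= 0.7, r+1 breaks it."""
        w = h = 32.0
        r = gaussian_radius(w, h, 0.7)
        base = BoundingBox(0, 0, w, h)

        def shifted_iou(delta):
            return iou(base, base.translate(delta, delta))

        assert shifted_iou(int(r)) >= 0.7
        assert shifted_iou(int(r) + 1) < 0.7

    def test_bad_overlap_rejected(self):
        with pytest.raises(ConfigurationError):
            gaussian_radius(8, 8, 1.2)


class TestEncodeHeatmap:
    def test_empty_annotation(self):
        ann = ImageAnnotation("a", 64, 64, [])
        assert not encode_heatmap(ann, 4).any()

    def test_center_encodes_to_one(self):
        ann = ImageAnnotation("a", 128, 128, [BoundingBox(32, 32, 96, 96)])
        H = encode_heatmap(ann, 4)
        assert H[16, 16] == 1.0

    def test_duplicate_boxes_idempotent(self):
        box = BoundingBox(20, 20, 60, 70)
        one = encode_heatmap(ImageAnnotation("a", 128, 128, [box]), 4)
        two = encode_heatmap(ImageAnnotation("a", 128, 128, [box, box]), 4)
        np.testing.assert_array_equal(one, two)

    def test_matches_brute_force_enumeration(self, rng):
        cfg = GaussianEncodingConfig()
        boxes, centers_radii = [], []
        for _ in range(4):
            w = rng.uniform(20, 80)
            h = rng.uniform(20, 80)
            x0 = rng.uniform(0, 128 - w)
            y0 = rng.uniform(0, 128 - h)
            box = BoundingBox(x0, y0, x0 + w, y0 + h)
            boxes.append(box)
            cx, cy = box.center
            centers_radii.append(
                ((int(cy / 4), int(cx / 4)), gaussian_radius(w / 4, h / 4, 0.7))
            )
        H = encode_heatmap(ImageAnnotation("a", 128, 128, boxes), 4, cfg)
        expected = brute_force_gaussian((32, 32), centers_radii, cfg.zero_threshold)
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_below_threshold_exactly_zero(self):
        ann = ImageAnnotation("a", 256, 256, [BoundingBox(0, 0, 200, 200)])
        H = encode_heatmap(ann, 4)
        nz = H[H > 0]
        assert nz.min() >= GaussianEncodingConfig().zero_threshold
        assert (H == 0).any()

    def test_out_of_grid_center_skipped(self, caplog):
        ann = ImageAnnotation("a", 64, 64, [BoundingBox(-40, -40, -2, -2)])
        with caplog.at_level("WARNING"):
            H = encode_heatmap(ann, 4)
        assert not H.any()
        assert "skipped" in caplog.text


class TestAllocateSamples:
    def test_all_zero_heatmap(self):
        alloc = allocate_samples(np.zeros((8, 8)), "expanded")
        assert alloc.positive_mask.sum() == 0
        assert alloc.negative_mask.all()

    def test_partition_and_counts_match_enumeration(self):
        ann = ImageAnnotation("a", 256, 256, [BoundingBox(40, 40, 180, 200)])
        H = encode_heatmap(ann, 4)
        expanded = allocate_samples(H, "expanded")
        original = allocate_samples(H, "original")
        k = int((H != 0).sum())
        assert k > 1
        assert expanded.positive_mask.sum() == k
        # one positive per distinct encoded center under the original strategy
        assert original.positive_mask.sum() == 1
        for alloc in (expanded, original):
            assert not (alloc.positive_mask & alloc.negative_mask).any()
            assert (alloc.positive_mask | alloc.negative_mask).all()
        # expanded strictly contains the original positives
        assert (expanded.positive_mask & original.positive_mask).sum() == 1
        np.testing.assert_array_equal(expanded.target_values, H)
        assert set(np.unique(original.target_values)) <= {0.0, 1.0}

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            allocate_samples(np.array([[1.5]]), "expanded")


def oracle_focal(pred, gt, alpha=2.0, beta=4.0, eps=1e-6):
    total = 0.0
    for p, g in zip(pred.ravel(), gt.ravel()):
        p = min(max(p, eps), 1 - eps)
        if g == 1.0:
            total += (1 - p) ** alpha * math.log(p)
        else:
            total += (1 - g) ** beta * p**alpha * math.log(1 - p)
    return -total / pred.size


def oracle_continuous(pred, gt, beta=2.0, eps=1e-6):
    total = 0.0
    for p, g in zip(pred.ravel(), gt.ravel()):
        p = min(max(p, eps), 1 - eps)
        total += abs(g - p) ** beta * ((1 - g) * math.log(1 - p) + g * math.log(p))
    return -total / pred.size


class TestLosses:
    @pytest.mark.parametrize(
        "loss, pred, gt, expected",
        [
            # direct substitutions, N = 1
            (modified_focal_loss, [[0.5]], [[1.0]], 0.25 * math.log(2)),
            (modified_focal_loss, [[0.5]], [[0.0]], 0.25 * math.log(2)),
            (continuous_label_loss, [[0.5]], [[1.0]], 0.25 * math.log(2)),
            (continuous_label_loss, [[0.5]], [[0.8]], 0.09 * math.log(2)),
        ],
    )
    def test_hand_computed_values(self, loss, pred, gt, expected):
        assert loss(np.array(pred), np.array(gt)) == pytest.approx(expected, abs=1e-9)

    def test_perfect_positive_is_near_zero(self):
        eps = LossConfig().eps
        v = modified_focal_loss(np.array([[1 - eps]]), np.array([[1.0]]))
        assert 0 <= v < 1e-10

    def test_matches_oracles_on_random_grids(self, rng):
        for _ in range(5):
            pred = rng.uniform(0.01, 0.99, size=(8, 8))
            gt = rng.uniform(0, 1, size=(8, 8))
            gt[rng.random(gt.shape) < 0.2] = 1.0
            gt[rng.random(gt.shape) < 0.2] = 0.0
            assert modified_focal_loss(pred, gt) == pytest.approx(
                oracle_focal(pred, gt), abs=1e-6
            )
            assert continuous_label_loss(pred, gt) == pytest.approx(
                oracle_continuous(pred, gt), abs=1e-6
            )

    def test_binary_consistency_elementwise(self, rng):
        """For H in {0,1} the continuous loss equals the focal loss pixelwise."""
        for _ in range(3):
            pred = rng.uniform(0.01, 0.99, size=(8, 8))
            gt = (rng.random((8, 8)) < 0.3).astype(float)
            for p, g in zip(pred.ravel(), gt.ravel()):
                a = modified_focal_loss(np.array([[p]]), np.array([[g]]))
                b = continuous_label_loss(np.array([[p]]), np.array([[g]]))
                assert a == pytest.approx(b, abs=1e-12)

    def test_continuous_zero_iff_equal(self, rng):
        gt = rng.uniform(0, 1, size=(6, 6))
        assert continuous_label_loss(gt.copy(), gt) == 0.0
        pred = gt.copy()
        pred[2, 3] = min(0.9, gt[2, 3] + 0.05)
        pred[2, 3] += 0.05
        assert continuous_label_loss(pred, gt) > 0.0

    def test_losses_nonnegative(self, rng):
        for _ in range(10):
            pred = rng.uniform(0, 1, size=(5, 5))
            gt = rng.uniform(0, 1, size=(5, 5))
            assert continuous_label_loss(pred, gt) >= 0.0
            assert modified_focal_loss(pred, np.round(gt)) >= 0.0

    def test_supervision_decays_with_distance_from_center(self):
        """Per-pixel penalty under constant prediction follows the Gaussian."""
        ann = ImageAnnotation("a", 256, 256, [BoundingBox(28, 28, 228, 228)])
        H = encode_heatmap(ann, 4)
        cy, cx = np.unravel_index(np.argmax(H), H.shape)
        c = 0.05  # constant prediction below all nonzero codes
        penalties = []
        for dx in range(0, 4):  # stay inside the Gaussian footprint
            h = H[cy, cx + dx]
            assert h > c
            penalties.append(
                continuous_label_loss(np.array([[c]]), np.array([[h]]))
            )
        assert all(a > b for a, b in zip(penalties, penalties[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            modified_focal_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBranchDispatch:
    def test_expanded_focal_rejected(self):
        H = np.zeros((4, 4))
        with pytest.raises(ConfigurationError, match="continuous"):
            heatmap_branch_loss(np.full((4, 4), 0.5), H, "expanded", "focal")

    def test_baseline_pairing_equals_focal(self, rng):
        gt = (rng.random((8, 8)) < 0.2).astype(float)
        pred = rng.uniform(0.01, 0.99, size=(8, 8))
        assert heatmap_branch_loss(pred, gt, "original", "focal") == pytest.approx(
            modified_focal_loss(pred, gt)
        )

    def test_expanded_continuous_pairing_zero_on_match(self):
        ann = ImageAnnotation("a", 128, 128, [BoundingBox(30, 30, 100, 100)])
        H = encode_heatmap(ann, 4)
        assert heatmap_branch_loss(H.copy(), H, "expanded", "continuous") == 0.0

    def test_expanded_continuous_pairing_matches_enumeration(self, rng):
        ann = ImageAnnotation("a", 128, 128, [BoundingBox(20, 30, 110, 90)])
        H = encode_heatmap(ann, 4)
        pred = np.full_like(H, 0.5)
        assert heatmap_branch_loss(pred, H, "expanded", "continuous") == pytest.approx(
            oracle_continuous(pred, H), abs=1e-9
        )
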