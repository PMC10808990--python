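"""Center-point heatmap supervision.

Ground truth for the heatmap branch is built by writing each object
center into a downsampled grid as an unnormalized 2-D Gaussian with peak
value 1, radius tied to box size, overlapping objects combined by
elementwise maximum, and codes below a zero threshold set to exactly 0.

Two positive/negative sample allocation strategies are supported:

* ``original`` — one positive per fruit, at the encoded center pixel
  (the classic center-point allocation, paired with the modified focal
  loss ``L = −1/N Σ [(1−Ĥ)^α log Ĥ if H=1;
  (1−H)^β Ĥ^α log(1−Ĥ) otherwise]``).
* ``expanded`` — every pixel with nonzero Gaussian code is positive,
  supervised with its continuous code value through the continuous
  label value loss ``L = −1/N Σ |H−Ĥ|^β [(1−H) log(1−Ĥ) + H log Ĥ]``.

For binary ground truth the two losses coincide (with the default
exponents α = β = 2), so the expanded allocation is a strict
generalization of the original one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import ImageAnnotation

log = logging.getLogger(__name__)

Strategy = Literal["original", "expanded"]
LossChoice = Literal["focal", "continuous"]


class ConfigurationError(ValueError):
    """Raised for incoherent supervision configurations."""


@dataclass(frozen=True)
class GaussianEncodingConfig:
    """Knobs of the Gaussian keypoint code.

    min_overlap
        IoU that a box perturbed by the Gaussian radius must keep with
        the original; sizes the radius (default 0.7).
    zero_threshold
        Code values strictly below this are set to exactly 0
        (default 2⁻⁷). Values equal to the threshold are kept, so
        "nonzero code ⇒ positive sample" holds literally.
    """

    min_overlap: float = 0.7
    zero_threshold: float = 2.0**-7

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap < 1.0:
            raise ConfigurationError(f"min_overlap {self.min_overlap} outside (0, 1)")
        if not 0.0 < self.zero_threshold < 1.0:
            raise ConfigurationError(f"zero_threshold {self.zero_threshold} outside (0, 1)")


@dataclass(frozen=True)
class LossConfig:
    """Exponents and numerics of the heatmap losses.

    ``alpha``/``beta_focal`` are the focusing and negative-down-weighting
    exponents of the modified focal loss (defaults 2 and 4);
    ``beta_cont`` is the modulating exponent of the continuous label
    value loss (default 2). ``normalization`` selects the literal
    total-pixel-count N (default) or the per-peak count used by the
    original center-point formulation, for cross-checking.
    """

    alpha: float = 2.0
    beta_focal: float = 4.0
    beta_cont: float = 2.0
    eps: float = 1e-6
    normalization: Literal["pixels", "peaks"] = "pixels"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta_focal, self.beta_cont) <= 0:
            raise ConfigurationError("loss exponents must be positive")
        if not 0.0 < self.eps <= 1e-3:
            raise ConfigurationError(f"eps {self.eps} outside (0, 1e-3]")


@dataclass
class SampleAllocation:
    """Positive/negative masks plus per-pixel supervision targets."""

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    target_values: np.ndarray
    strategy: Strategy


def gaussian_radius(
    box_width: float, box_height: float, min_overlap: float = 0.7
) -> float:
    """Largest radius keeping IoU ≥ *min_overlap* under corner perturbation.

    Dimensions are in heatmap-scale pixels. The radius is the minimum of
    the three standard quadratic-root cases (both corners out, both in,
    one in / one out), floored at 0; degenerate boxes get radius 0.
    """
    if not 0.0 < min_overlap < 1.0:
        raise ConfigurationError(f"min_overlap {min_overlap} outside (0, 1)")
    if box_width < 0 or box_height < 0:
        raise ValueError("negative box dimensions")
    if box_width == 0 or box_height == 0:
        return 0.0
    w, h = box_width, box_height

    a1 = 1.0
    b1 = h + w
    c1 = w * h * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - math.sqrt(b1 * b1 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (h + w)
    c2 = (1 - min_overlap) * w * h
    r2 = (b2 - math.sqrt(b2 * b2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (h + w)
    c3 = (min_overlap - 1) * w * h
    r3 = (-b3 + math.sqrt(b3 * b3 - 4 * a3 * c3)) / (2 * a3)

    return max(0.0, min(r1, r2, r3))


def gaussian_patch(radius: float) -> np.ndarray:
    """Square unnormalized Gaussian of side ``2⌊radius⌋+1``, peak 1, σ = radius/3."""
    ri = int(radius)
    if ri <= 0:
        return np.ones((1, 1))
    sigma = radius / 3.0
    y, x = np.ogrid[-ri : ri + 1, -ri : ri + 1]
    return np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))


def encode_heatmap(
    annotation: ImageAnnotation,
    r: int,
    config: GaussianEncodingConfig = GaussianEncodingConfig(),
    boxes=None,
) -> np.ndarray:
    """Encode object centers into a ground-truth heatmap at factor *r*.

    Returns a float array of shape ``(ceil(H/r), ceil(W/r))`` with one
    Gaussian per box (peak exactly 1 at the integer heatmap cell of the
    box center), combined by elementwise maximum, then thresholded to 0
    below ``config.zero_threshold``. Boxes whose center falls outside
    the grid after downsampling are skipped with a warning. If *boxes*
    is given it overrides ``annotation.boxes`` (used for per-layer
    routing).
    """
    hh = -(-annotation.height // r)
    hw = -(-annotation.width // r)
    heat = np.zeros((hh, hw), dtype=np.float64)
    use_boxes = annotation.boxes if boxes is None else boxes
    for box in use_boxes:
        cx, cy = box.center
        ix, iy = int(cx / r), int(cy / r)
        if not (0 <= ix < hw and 0 <= iy < hh):
            log.warning(
                "image %s: box center (%.1f, %.1f) outside %dx%d grid at r=%d; skipped",
                annotation.image_id, cx, cy, hw, hh, r,
            )
            continue
        radius = gaussian_radius(box.width / r, box.height / r, config.min_overlap)
        patch = gaussian_patch(radius)
        ri = patch.shape[0] // 2
        top, bot = max(0, iy - ri), min(hh, iy + ri + 1)
        left, right = max(0, ix - ri), min(hw, ix + ri + 1)
        view = heat[top:bot, left:right]
        pview = patch[
            top - (iy - ri) : patch.shape[0] - ((iy + ri + 1) - bot),
            left - (ix - ri) : patch.shape[1] - ((ix + ri + 1) - right),
        ]
        np.maximum(view, pview, out=view)
    heat[heat < config.zero_threshold] = 0.0
    return heat


def _validate_heatmap(H: np.ndarray) -> None:
    if H.min() < 0.0 or H.max() > 1.0:
        raise ValueError("heatmap values outside [0, 1]")


def allocate_samples(H: np.ndarray, strategy: Strategy = "expanded") -> SampleAllocation:
    """Partition heatmap pixels into positive and negative samples.

    ``expanded``: every nonzero-coded pixel is positive, with its code
    value as supervision target. ``original``: only exact-center pixels
    (code 1) are positive and targets are binarized to {0, 1}.
    """
    _validate_heatmap(H)
    if strategy == "expanded":
        pos = H != 0.0
        targets = H.copy()
    elif strategy == "original":
        pos = H == 1.0
        targets = pos.astype(H.dtype)
    else:
        raise ConfigurationError(f"unknown allocation strategy {strategy!r}")
    return SampleAllocation(
        positive_mask=pos,
        negative_mask=~pos,
        target_values=targets,
        strategy=strategy,
    )


def _normalizer(gt: np.ndarray, config: LossConfig) -> float:
    if config.normalization == "pixels":
        return float(gt.size)
    return float(max(1, int((gt == 1.0).sum())))


def modified_focal_loss(
    pred: np.ndarray, gt: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Penalty-reduced focal loss for binary-labeled center supervision."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = np.clip(pred, config.eps, 1.0 - config.eps)
    pos = gt == 1.0
    pos_term = np.where(pos, (1.0 - p) ** config.alpha * np.log(p), 0.0)
    neg_term = np.where(
        pos, 0.0, (1.0 - gt) ** config.beta_focal * p**config.alpha * np.log(1.0 - p)
    )
    return float(-(pos_term + neg_term).sum() / _normalizer(gt, config))


def continuous_label_loss(
    pred: np.ndarray, gt: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Cross-entropy modulated by |H − Ĥ|^β; labels may be any value in [0, 1]."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = np.clip(pred, config.eps, 1.0 - config.eps)
    # modulating factor from the raw prediction: exact zero at pred == gt
    mod = np.abs(gt - pred) ** config.beta_cont
    ce = (1.0 - gt) * np.log(1.0 - p) + gt * np.log(p)
    return float(-(mod * ce).sum() / _normalizer(gt, config))


def heatmap_branch_loss(
    pred: np.ndarray,
    gt: np.ndarray,
    allocation_strategy: Strategy = "expanded",
    loss_choice: LossChoice = "continuous",
    config: LossConfig = LossConfig(),
) -> float:
    """Dispatch to the configured heatmap loss.

    The expanded allocation pairs only with the continuous label value
    loss: under a binary-label loss the off-center positives would be
    indistinguishable from the centers, defeating accurate center
    localization, so ``(expanded, focal)`` is rejected.
    """
    if loss_choice == "focal":
        if allocation_strategy == "expanded":
            raise ConfigurationError(
                "expanded allocation with the focal loss is incoherent: binary "
                "labels give off-center positives the same supervision strength "
                "as true centers; use the continuous label value loss"
            )
        alloc = allocate_samples(gt, allocation_strategy)
        return modified_focal_loss(pred, alloc.target_values, config)
    if loss_choice == "continuous":
        alloc = allocate_samples(gt, allocation_strategy)
        return continuous_label_loss(pred, alloc.target_values, config)
    raise ConfigurationError(f"unknown loss choice {loss_choice!r}")


def write_heatmap_png(H: np.ndarray, path) -> None:
    """Debug dump of a heatmap as 16-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(H, 0.0, 1.0)
    Image.fromarray((arr * 65535).astype(np.uint16)).save(path)
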