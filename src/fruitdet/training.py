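"""Target construction, loss assembly, and the optimization loop.

Objects are routed to exactly one prediction layer by the small-object
rule (area < 32² px or √(relative area) < 3%): small fruits go to the
high-resolution 2× layer, everything else to the 4× layer. The total
objective is

    L = λ_heat Σ_ℓ L_H(ℓ) + λ_size Σ_ℓ L1_size(ℓ) + λ_off Σ_ℓ L1_off(ℓ)

with the heatmap term chosen by the configured allocation strategy and
loss, and the size/offset L1 terms supervised only at encoded center
pixels (the allocation expansion applies to the heatmap branch alone).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import BoundingBox, ImageAnnotation
from .heatmap import (
    ConfigurationError,
    GaussianEncodingConfig,
    LossConfig,
    encode_heatmap,
)
from .model import Detector, ModelConfig
from .nn import Adam
from .nn.autograd import DTYPE, Tensor

log = logging.getLogger(__name__)

SMALL_AREA = 32 * 32
SMALL_REL_SQRT = 0.03


def is_small_object(box: BoundingBox, image_width: float, image_height: float) -> bool:
    """Small iff pixel area < 32×32 or √(area / image area) < 3%."""
    if image_width <= 0 or image_height <= 0:
        raise ValueError("zero-area image")
    area = box.area
    return area < SMALL_AREA or math.sqrt(area / (image_width * image_height)) < SMALL_REL_SQRT


@dataclass
class LayerTargets:
    """Per-layer supervision targets plus the object routing record."""

    heat: dict[int, np.ndarray]
    size: dict[int, np.ndarray]
    offset: dict[int, np.ndarray]
    center_mask: dict[int, np.ndarray]
    routing: list[int]  # layer id per GT box


def build_layer_targets(
    annotation: ImageAnnotation,
    encoding: GaussianEncodingConfig = GaussianEncodingConfig(),
    layer_factors: dict[int, int] | None = None,
) -> LayerTargets:
    """Route boxes to layers and build heat/size/offset targets.

    With a single configured layer every object routes there; with the
    double-layer setup small objects go to layer 1 (r=2).
    """
    if layer_factors is None:
        layer_factors = {1: 2, 2: 4}
    layers = sorted(layer_factors)
    routing = []
    routed: dict[int, list[BoundingBox]] = {l: [] for l in layers}
    for box in annotation.boxes:
        if len(layers) == 1:
            layer = layers[0]
        else:
            layer = 1 if is_small_object(box, annotation.width, annotation.height) else 2
        routing.append(layer)
        routed[layer].append(box)

    heat, size, offset, mask = {}, {}, {}, {}
    for layer in layers:
        r = layer_factors[layer]
        H = encode_heatmap(annotation, r, encoding, boxes=routed[layer])
        heat[layer] = H
        hh, hw = H.shape
        size[layer] = np.zeros((2, hh, hw), dtype=np.float64)
        offset[layer] = np.zeros((2, hh, hw), dtype=np.float64)
        mask[layer] = np.zeros((hh, hw), dtype=bool)
        for box in routed[layer]:
            cx, cy = box.center
            ix, iy = int(cx / r), int(cy / r)
            if not (0 <= ix < hw and 0 <= iy < hh):
                continue
            size[layer][:, iy, ix] = (box.width, box.height)  # input-image pixels
            offset[layer][:, iy, ix] = (cx / r - ix, cy / r - iy)
            mask[layer][iy, ix] = True
    return LayerTargets(heat, size, offset, mask, routing)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe; defaults follow the full-scale published setup."""

    batch_size: int = 4
    initial_lr: float = 0.000125
    epochs: int = 100
    lr_drop_epoch: int = 90
    lr_drop_factor: float = 10.0
    lambda_heat: float = 1.0
    lambda_size: float = 0.1
    lambda_off: float = 1.0
    seed: int = 0
    allocation_strategy: str = "expanded"
    loss_choice: str = "continuous"
    neck_variant: str = "cropped_double"
    eval_every: int = 10
    encoding: GaussianEncodingConfig = field(default_factory=GaussianEncodingConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ConfigurationError("initial_lr must be positive")
        if self.lr_drop_epoch > self.epochs:
            raise ConfigurationError("lr_drop_epoch must not exceed epochs")
        if self.allocation_strategy == "expanded" and self.loss_choice == "focal":
            raise ConfigurationError(
                "expanded allocation requires the continuous label value loss"
            )

    def lr_at_epoch(self, epoch: int) -> float:
        """1-based epoch; the drop applies from lr_drop_epoch on."""
        if epoch >= self.lr_drop_epoch:
            return self.initial_lr / self.lr_drop_factor
        return self.initial_lr


# -- differentiable losses (mirror the numpy reference in heatmap.py) --


def _heat_loss_tensor(pred: Tensor, gt: np.ndarray, strategy: str, choice: str,
                      cfg: LossConfig) -> Tensor:
    if strategy == "expanded" and choice == "focal":
        raise ConfigurationError(
            "expanded allocation requires the continuous label value loss"
        )
    gt = gt.astype(DTYPE)
    if strategy == "original":
        targets = (gt == 1.0).astype(DTYPE)
    else:
        targets = gt
    if cfg.normalization == "pixels":
        n = float(gt.size)
    else:
        n = float(max(1, int((gt == 1.0).sum())))
    p = pred.clip(cfg.eps, 1.0 - cfg.eps)
    if choice == "continuous":
        mod = (targets - pred).abs() ** cfg.beta_cont
        ce = (1.0 - targets) * (1.0 - p).log() + targets * p.log()
        return -(mod * ce).sum() * (1.0 / n)
    pos = targets == 1.0
    pos_term = pos * ((1.0 - p) ** cfg.alpha) * p.log()
    neg_term = (~pos) * ((1.0 - targets) ** cfg.beta_focal) * (p ** cfg.alpha) * (1.0 - p).log()
    return -(pos_term + neg_term).sum() * (1.0 / n)


def _masked_l1(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    count = float(max(1, int(mask.sum())))
    return ((pred - target.astype(DTYPE)).abs() * mask.astype(DTYPE)).sum() * (1.0 / count)


def total_loss(
    outputs: dict[int, dict[str, Tensor]],
    targets: dict[int, LayerTargets] | list[LayerTargets],
    cfg: TrainConfig,
) -> tuple[Tensor, dict[str, float]]:
    """Assemble the weighted objective over a batch.

    *outputs* are per-layer head outputs for a batch of N images;
    *targets* is the list of per-image LayerTargets (stacked here).
    """
    if isinstance(targets, LayerTargets):
        targets = [targets]
    loss_t = None
    breakdown = {"heat": 0.0, "size": 0.0, "offset": 0.0}
    for layer, out in outputs.items():
        gt_heat = np.stack([t.heat[layer] for t in targets])[:, None]
        gt_size = np.stack([t.size[layer] for t in targets])
        gt_off = np.stack([t.offset[layer] for t in targets])
        mask = np.stack([t.center_mask[layer] for t in targets])[:, None]

        l_heat = _heat_loss_tensor(
            out["heat"], gt_heat, cfg.allocation_strategy, cfg.loss_choice, cfg.loss
        )
        l_size = _masked_l1(out["size"], gt_size, mask)
        l_off = _masked_l1(out["offset"], gt_off, mask)
        term = cfg.lambda_heat * l_heat + cfg.lambda_size * l_size + cfg.lambda_off * l_off
        loss_t = term if loss_t is None else loss_t + term
        breakdown["heat"] += float(l_heat.data)
        breakdown["size"] += float(l_size.data)
        breakdown["offset"] += float(l_off.data)
    breakdown["total"] = float(loss_t.data)
    if not np.isfinite(breakdown["total"]):
        raise FloatingPointError(
            f"non-finite loss: {breakdown}; gt stats "
            f"min={min(float(np.min(t.heat[l])) for t in targets for l in t.heat)}"
        )
    return loss_t, breakdown


@dataclass
class TrainResult:
    model: Detector
    history: list[dict]


def train(
    dataset: list[tuple[np.ndarray, ImageAnnotation]],
    cfg: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
    val_dataset: list[tuple[np.ndarray, ImageAnnotation]] | None = None,
    out_dir: str | Path | None = None,
    checkpoint_every: int = 0,
) -> TrainResult:
    """Run the optimization loop; deterministic for a fixed seed.

    Images are HWC uint8 and must share one size divisible by the
    model's padding multiple so per-layer targets align with the head
    outputs.
    """
    if not dataset:
        raise ConfigurationError("empty training dataset")
    if model_config is None:
        model_config = ModelConfig(variant=cfg.neck_variant, seed=cfg.seed)
    elif model_config.variant != cfg.neck_variant:
        model_config = replace(model_config, variant=cfg.neck_variant)

    model = Detector(model_config)
    h0, w0 = dataset[0][0].shape[:2]
    if h0 % model.pad_multiple or w0 % model.pad_multiple:
        raise ConfigurationError(
            f"training image size {w0}x{h0} must be a multiple of {model.pad_multiple}"
        )

    factors = model.layer_factors
    images = np.stack([im for im, _ in dataset]).astype(DTYPE).transpose(0, 3, 1, 2) / 255.0
    targets = [build_layer_targets(ann, cfg.encoding, factors) for _, ann in dataset]

    opt = Adam([p for p in model.parameters()], lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    n = len(dataset)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        sums = {"total": 0.0, "heat": 0.0, "size": 0.0, "offset": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            outputs = model.forward(images[idx])
            loss_t, breakdown = total_loss(outputs, [targets[i] for i in idx], cfg)
            model.zero_grad()
            loss_t.backward()
            opt.step()
            for k in sums:
                sums[k] += breakdown[k]
            n_batches += 1
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            **{k: sums[k] / n_batches for k in sums},
        }
        if val_dataset and cfg.eval_every and epoch % cfg.eval_every == 0:
            record["val_ap"] = _validation_ap(model, val_dataset)
            model.set_training(True)
        history.append(record)
        log.info("epoch %d: %s", epoch, record)
        if out_dir is not None:
            with open(out_dir / "metrics.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
            if checkpoint_every and epoch % checkpoint_every == 0:
                model.save(out_dir / f"checkpoint_ep{epoch:04d}.npz")

    model.set_training(False)
    if out_dir is not None:
        model.save(out_dir / "checkpoint_final.npz")
    return TrainResult(model, history)


def _validation_ap(model, val_dataset) -> float:
    from .evaluation import evaluate
    from .inference import DecodeConfig, detect_image

    model.set_training(False)
    cfg = DecodeConfig(score_threshold=0.05)
    dets = [detect_image(model, im, cfg) for im, _ in val_dataset]
    gts = [ann for _, ann in val_dataset]
    return evaluate(dets, gts).ap
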