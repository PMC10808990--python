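"""Decode heatmaps into scored boxes, merge layers, export pseudo-labels.

Peaks are pixels equal to their local-window maximum (the classic
center-point decoding); each peak becomes a box via the sub-pixel offset
and size maps. Detections from the 2× and 4× layers are merged with a
greedy cross-layer IoU NMS that keeps the higher-scoring duplicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import maximum_filter

from .annotations import write_annotations
from .geometry import BoundingBox, Detection, ImageAnnotation, iou

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecodeConfig:
    top_k: int = 100
    score_threshold: float = 0.3
    peak_window: int = 3
    cross_layer_nms_iou: float = 0.5  # 1.0 disables suppression

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0.0 <= self.score_threshold <= 1.0 and 0.0 <= self.cross_layer_nms_iou <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


def decode_layer(
    outputs: dict[str, np.ndarray],
    r: int,
    image_size: tuple[int, int],
    config: DecodeConfig = DecodeConfig(),
    source_layer: int = 2,
) -> list[Detection]:
    """Decode one layer's maps into detections for a single image.

    *outputs* holds ``heat`` (h, w), ``size`` (2, h, w) in input-image
    pixels and ``offset`` (2, h, w) in heatmap-cell units; *image_size*
    is (W, H) of the unpadded image for clipping.
    """
    heat = np.asarray(outputs["heat"], dtype=np.float64)
    if heat.ndim == 3:
        heat = heat[0]
    size_map = np.asarray(outputs["size"], dtype=np.float64)
    off_map = np.asarray(outputs["offset"], dtype=np.float64)
    w_img, h_img = image_size

    peaks = heat >= maximum_filter(heat, size=config.peak_window, mode="constant")
    peaks &= heat >= config.score_threshold
    ys, xs = np.nonzero(peaks)
    if len(ys) == 0:
        return []
    scores = heat[ys, xs]
    if len(scores) > config.top_k:
        keep = np.argsort(-scores, kind="stable")[: config.top_k]
        ys, xs, scores = ys[keep], xs[keep], scores[keep]

    dets = []
    for y, x, s in zip(ys, xs, scores):
        cx = (x + off_map[0, y, x]) * r
        cy = (y + off_map[1, y, x]) * r
        bw = max(0.0, size_map[0, y, x])
        bh = max(0.0, size_map[1, y, x])
        box = BoundingBox(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)
        box = box.clip(w_img, h_img)
        if box.area <= 0.0:  # degenerate after clipping; cannot match anything
            continue
        dets.append(Detection(box, float(min(1.0, s)), source_layer))
    dets.sort(key=_det_order)
    return dets


def _det_order(d: Detection):
    return (-d.score, d.source_layer, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)


def merge_layers(
    dets1: list[Detection],
    dets2: list[Detection],
    config: DecodeConfig = DecodeConfig(),
) -> list[Detection]:
    """Union of both layers with greedy IoU NMS, higher score wins."""
    pool = sorted(dets1 + dets2, key=_det_order)
    kept: list[Detection] = []
    for d in pool:
        if all(iou(d.box, k.box) <= config.cross_layer_nms_iou for k in kept):
            kept.append(d)
    return kept


def detect_image(
    model, image: np.ndarray, config: DecodeConfig = DecodeConfig()
) -> list[Detection]:
    """Run the full detector on one HWC uint8 image."""
    model.set_training(False)
    h, w = image.shape[:2]
    batch = image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    outputs = model.forward(batch)
    per_layer = []
    for layer, r in model.layer_factors.items():
        out_np = {k: v.data[0] for k, v in outputs[layer].items()}
        per_layer.append(decode_layer(out_np, r, (w, h), config, source_layer=layer))
    if len(per_layer) == 1:
        return sorted(per_layer[0], key=_det_order)
    return merge_layers(per_layer[0], per_layer[1], config)


RefinementHook = Callable[[list[ImageAnnotation], list[list[Detection]]],
                          list[ImageAnnotation]]


def export_pseudo_labels(
    model,
    image_paths: list[str | Path],
    out_path: str | Path,
    dialect: str = "coco",
    config: DecodeConfig = DecodeConfig(),
    refinement_hook: RefinementHook | None = None,
) -> dict:
    """Detect on unlabeled images and write the results as annotations.

    *refinement_hook*, if given, may filter or update the pseudo-labels
    before writing (a plug-in point for external threshold-selection
    strategies). Returns a summary of images processed, boxes written,
    and the detection-score distribution.
    """
    from PIL import Image

    annotations: list[ImageAnnotation] = []
    all_dets: list[list[Detection]] = []
    scores: list[float] = []
    skipped = 0
    for path in image_paths:
        path = Path(path)
        try:
            image = np.asarray(Image.open(path).convert("RGB"))
        except OSError as exc:
            log.warning("skipping unreadable image %s: %s", path, exc)
            skipped += 1
            continue
        dets = detect_image(model, image, config)
        all_dets.append(dets)
        scores.extend(d.score for d in dets)
        annotations.append(
            ImageAnnotation(
                image_id=path.stem,
                width=image.shape[1],
                height=image.shape[0],
                boxes=[d.box for d in dets],
            )
        )
    if refinement_hook is not None:
        annotations = refinement_hook(annotations, all_dets)
    write_annotations(annotations, out_path, dialect)
    arr = np.asarray(scores) if scores else np.zeros(0)
    return {
        "images_processed": len(annotations),
        "images_skipped": skipped,
        "boxes_written": int(sum(len(a.boxes) for a in annotations)),
        "score_mean": float(arr.mean()) if arr.size else None,
        "score_min": float(arr.min()) if arr.size else None,
        "score_max": float(arr.max()) if arr.size else None,
    }
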