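"""Seeded generator of orchard-like scenes with ground-truth boxes.

Scenes emulate the two domain gaps the detector is designed to bridge,
without any photorealism:

* **foreground (scale) gap** — a ``source_like`` regime draws fruit
  diameters from a narrow log-normal around 16% of the image side,
  while ``target_like`` mixes a wide log-normal with an explicit
  fraction of small objects (area < 32² px or √(relative area) < 3%)
  and stretches aspect ratios toward elliptical fruit;
* **background gap** — two styles differing in palette, gradient and
  distractor shapes (leaf-like ellipses vs. branch-like strokes).

Fruits are shaded, axis-aligned ellipses, so every annotation box is
exactly tight to the unoccluded (amodal) fruit extent; fruits whose
visible fraction falls below a cutoff are dropped from the annotation.
Generation is bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .annotations import read_annotations, write_annotations
from .geometry import BoundingBox, ImageAnnotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneConfig:
    width: int = 256
    height: int = 256
    fruits_min: int = 3
    fruits_max: int = 8
    scale_regime: str = "source_like"  # or "target_like"
    small_fraction: float = 0.5  # target_like only
    rel_diameter: float = 0.16  # median diameter / min(W, H), source regime
    source_sigma: float = 0.08  # log-space spread, narrow
    target_sigma: float = 0.45  # log-space spread, wide
    aspect_min: float = 1.0
    aspect_max: float = 1.15
    background_style: str = "style_A"  # or "style_B"
    occlusion_prob: float = 0.15
    max_occluded_fraction: float = 0.5
    min_visible_fraction: float = 0.25
    base_color: tuple[int, int, int] = (214, 94, 48)  # orange-like fruit
    color_jitter: float = 0.12

    def __post_init__(self) -> None:
        if self.scale_regime not in ("source_like", "target_like"):
            raise ValueError(f"unknown scale regime {self.scale_regime!r}")
        if self.background_style not in ("style_A", "style_B"):
            raise ValueError(f"unknown background style {self.background_style!r}")
        if not 0.0 <= self.small_fraction <= 1.0:
            raise ValueError("small_fraction outside [0, 1]")


def target_like_config(base: SceneConfig = SceneConfig(), **overrides) -> SceneConfig:
    """The gap-side counterpart of a source config.

    The gap spans the axes the detector is designed to bridge: a wide
    fruit-scale distribution with small objects, a different background
    style, and stretched (elliptical) aspect ratios. Fruit appearance
    itself is kept, since translating appearance across species is the
    job of a separate image-translation stage, not of the detector.
    """
    return replace(
        base,
        scale_regime="target_like",
        background_style="style_B",
        aspect_max=1.8,
        **overrides,
    )


def _sample_diameter(cfg: SceneConfig, rng: np.random.Generator) -> float:
    s = min(cfg.width, cfg.height)
    if cfg.scale_regime == "source_like":
        d = cfg.rel_diameter * s * rng.lognormal(0.0, cfg.source_sigma)
    elif rng.random() < cfg.small_fraction:
        # guaranteed small: bounding square area < 32x32
        d = rng.uniform(max(6.0, 0.08 * s), 30.0)
    else:
        # guaranteed not small: area >= 32x32 and sqrt(rel area) >= 3%
        lo = max(34.0, 0.032 * math.sqrt(cfg.width * cfg.height))
        hi = max(lo + 2.0, 0.35 * s)
        d = math.exp(rng.normal(math.log(0.6 * (lo + hi) / 2), cfg.target_sigma))
        d = min(max(d, lo), hi)
    return min(d, 0.9 * s)


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    yy = np.linspace(0.0, 1.0, h)[:, None, None]
    if cfg.background_style == "style_A":
        top = np.array([96, 136, 70], dtype=np.float64)  # foliage green
        bottom = np.array([56, 88, 42], dtype=np.float64)
    else:
        top = np.array([150, 166, 180], dtype=np.float64)  # hazy sky gray-blue
        bottom = np.array([108, 84, 58], dtype=np.float64)  # soil brown
    img = top * (1 - yy) + bottom * yy
    img = np.broadcast_to(img, (h, w, 3)).copy()
    img += rng.normal(0.0, 6.0, size=(h, w, 1))

    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    if cfg.background_style == "style_A":
        for _ in range(10):  # leaf-like ellipses
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            a = rng.uniform(0.04, 0.12) * w
            b = a * rng.uniform(0.35, 0.6)
            mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
            shade = rng.uniform(-30, 25)
            img[mask] += np.array([shade * 0.5, shade, shade * 0.4])
    else:
        for _ in range(6):  # branch-like strokes
            x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
            ang = rng.uniform(0, math.pi)
            ux, uy = math.cos(ang), math.sin(ang)
            t = (X - x0) * ux + (Y - y0) * uy
            dist = np.abs(-(X - x0) * uy + (Y - y0) * ux)
            mask = (dist < rng.uniform(1.5, 4.0)) & (np.abs(t) < rng.uniform(0.2, 0.6) * w)
            img[mask] = np.array([72, 52, 36]) + rng.normal(0, 5, 3)
    return img


def _draw_stroke(owner, img, cx, cy, length, width_px, ang, color):
    h, w = owner.shape
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    ux, uy = math.cos(ang), math.sin(ang)
    t = (X - cx) * ux + (Y - cy) * uy
    dist = np.abs(-(X - cx) * uy + (Y - cy) * ux)
    mask = (dist < width_px / 2) & (np.abs(t) < length / 2)
    owner[mask] = -1
    img[mask] = color
    return mask


def generate_scene(
    config: SceneConfig, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, ImageAnnotation]:
    """Render one scene; returns (HWC uint8 image, annotation)."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    img = _background(config, rng)
    owner = np.zeros((h, w), dtype=np.int32)  # 0 bg, i+1 fruit i, -1 occluder
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)

    n_fruits = int(rng.integers(config.fruits_min, config.fruits_max + 1))
    fruit_boxes: list[BoundingBox] = []
    fruit_masks: list[np.ndarray] = []
    for i in range(n_fruits):
        d = _sample_diameter(config, rng)
        ar = rng.uniform(config.aspect_min, config.aspect_max)
        a = d / 2 * math.sqrt(ar)
        b = d / 2 / math.sqrt(ar)
        if rng.random() < 0.5:
            a, b = b, a
        lo_x, hi_x = min(a, w - a), max(a, w - a)
        lo_y, hi_y = min(b, h - b), max(b, h - b)
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)

        rho2 = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2
        mask = rho2 <= 1.0
        if not mask.any():
            log.info("degenerate fruit placement skipped (d=%.1f)", d)
            continue
        color = np.asarray(config.base_color, dtype=np.float64)
        color = color * (1.0 + rng.uniform(-config.color_jitter, config.color_jitter, 3))
        shading = 0.55 + 0.45 * (1.0 - np.sqrt(np.clip(rho2, 0, 1)))
        # specular highlight toward the upper-left of the fruit
        hl = np.exp(-(((X - (cx - 0.35 * a)) / (0.35 * a)) ** 2
                      + ((Y - (cy - 0.35 * b)) / (0.35 * b)) ** 2))
        px = color[None, :] * shading[mask][:, None] + 70.0 * hl[mask][:, None]
        img[mask] = px
        owner[mask] = i + 1
        fruit_masks.append(mask)
        fruit_boxes.append(
            BoundingBox(cx - a, cy - b, cx + a, cy + b).clip(w, h)
        )

        if rng.random() < config.occlusion_prob:
            frac = rng.uniform(0.1, config.max_occluded_fraction)
            _draw_stroke(
                owner, img, cx, cy,
                length=2.2 * max(a, b),
                width_px=2 * frac * min(a, b),
                ang=rng.uniform(0, math.pi),
                color=np.array([70, 54, 40]) + rng.normal(0, 4, 3),
            )

    boxes = []
    for i, (box, mask) in enumerate(zip(fruit_boxes, fruit_masks)):
        visible = (owner[mask] == i + 1).mean()
        if visible >= config.min_visible_fraction:
            boxes.append(box)
        else:
            log.info("fruit %d dropped: visible fraction %.2f", i, visible)

    image = np.clip(img, 0, 255).astype(np.uint8)
    ann = ImageAnnotation(image_id="scene", width=w, height=h, boxes=boxes)
    return image, ann


def _scene_seed(seed: int, split_index: int, image_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(split_index, image_index))


def generate_split(
    config: SceneConfig, n: int, seed: int, split_index: int = 0
) -> list[tuple[np.ndarray, ImageAnnotation]]:
    """Generate *n* scenes in memory with per-image derived seeds."""
    out = []
    for i in range(n):
        image, ann = generate_scene(config, _scene_seed(seed, split_index, i))
        ann.image_id = f"img_{split_index}_{i:05d}"
        out.append((image, ann))
    return out


def generate_benchmark(
    out_dir: str | Path,
    train_config: SceneConfig,
    test_config: SceneConfig,
    n_train: int,
    n_test: int,
    seed: int,
    n_test_in_distribution: int = 0,
    overwrite: bool = False,
) -> dict:
    """Write a train/test benchmark with a domain gap between the splits.

    Optionally adds a ``test_id`` split drawn from the training
    distribution, for measuring in-distribution performance next to the
    gap split. Returns the manifest (also written to disk).
    """
    from PIL import Image

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")

    splits = {"train": (train_config, n_train, 0), "test": (test_config, n_test, 1)}
    if n_test_in_distribution:
        splits["test_id"] = (train_config, n_test_in_distribution, 2)

    manifest: dict = {"seed": seed, "splits": {}}
    for name, (cfg, n, split_index) in splits.items():
        img_dir = out_dir / name / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        data = generate_split(cfg, n, seed, split_index)
        for image, ann in data:
            Image.fromarray(image).save(img_dir / f"{ann.image_id}.png")
        write_annotations([ann for _, ann in data], out_dir / name / "annotations.json", "coco")
        manifest["splits"][name] = {
            "n": n,
            "split_index": split_index,
            "config": asdict(cfg),
            "boxes": int(sum(len(a.boxes) for _, a in data)),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_split(split_dir: str | Path) -> list[tuple[np.ndarray, ImageAnnotation]]:
    """Read back a generated split (PNG images + COCO annotations)."""
    from PIL import Image

    split_dir = Path(split_dir)
    anns = read_annotations(split_dir / "annotations.json", "coco")
    out = []
    for ann in anns:
        image = np.asarray(Image.open(split_dir / "images" / f"{ann.image_id}.png"))
        out.append((image, ann))
    return out
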