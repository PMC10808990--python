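"""Core spatial types for single-class fruit detection.

Coordinate convention: boxes are axis-aligned, continuous, 0-based and
half-open — a box covers ``[x_min, x_max) × [y_min, y_max)`` in pixel
space. This makes COCO ``[x, y, w, h]`` arithmetic exact and keeps the
mapping from image pixels to downsampled heatmap cells unambiguous.
Pascal VOC's 1-based inclusive convention is converted at the file
boundary, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, width: float, height: float) -> "BoundingBox":
        """Clip to an image of size ``width × height``. Idempotent."""
        return BoundingBox(
            min(max(self.x_min, 0.0), width),
            min(max(self.y_min, 0.0), height),
            min(max(self.x_max, 0.0), width),
            min(max(self.y_max, 0.0), height),
        )

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy
        )


FRUIT_CLASS = "fruit"


@dataclass
class ImageAnnotation:
    """Ground-truth boxes for one image; single class ``"fruit"``."""

    image_id: str
    width: int
    height: int
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"image {self.image_id!r}: non-positive size "
                f"{self.width}x{self.height}"
            )

    def clipped(self) -> "ImageAnnotation":
        return ImageAnnotation(
            self.image_id,
            self.width,
            self.height,
            [b.clip(self.width, self.height) for b in self.boxes],
        )


@dataclass(frozen=True)
class Detection:
    """A scored box from one of the two prediction layers."""

    box: BoundingBox
    score: float
    source_layer: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.source_layer not in (1, 2):
            raise ValueError(f"source_layer must be 1 or 2, got {self.source_layer}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union; 0 for disjoint or zero-area operands."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union
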