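"""Readers and writers for COCO JSON and Pascal VOC XML annotations.

Both dialects are converted to the package's internal 0-based half-open
convention at the boundary:

* COCO ``bbox = [x, y, w, h]``  →  ``(x, y, x + w, y + h)``
* VOC 1-based inclusive ``xmin..xmax``  →  ``(xmin − 1, ymin − 1, xmax, ymax)``

Only the single class ``"fruit"`` is carried; degenerate (zero-area)
ground-truth boxes are rejected at read time with a warning rather than
silently kept.
"""

from __future__ import annotations

import json
import logging
import os
import xml.etree.ElementTree as ET
from pathlib import Path

from .geometry import FRUIT_CLASS, BoundingBox, ImageAnnotation

log = logging.getLogger(__name__)

DIALECTS = ("coco", "voc")


class AnnotationParseError(ValueError):
    """Raised when an annotation file does not parse under its dialect."""


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown annotation dialect {dialect!r}; expected one of {DIALECTS}")


def read_annotations(path: str | os.PathLike, dialect: str) -> list[ImageAnnotation]:
    """Read annotations from *path*.

    For ``coco`` the path is a single JSON file covering many images; for
    ``voc`` it may be a single XML file or a directory of per-image XML
    files.
    """
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "coco":
        return _read_coco(path)
    if path.is_dir():
        anns = [_read_voc_file(p) for p in sorted(path.glob("*.xml"))]
        return anns
    return [_read_voc_file(path)]


def write_annotations(
    annotations: list[ImageAnnotation], path: str | os.PathLike, dialect: str
) -> None:
    """Write annotations to *path*.

    ``coco``: one JSON file. ``voc``: *path* is a directory receiving one
    XML file per image, named ``<image_id>.xml``.
    """
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "coco":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(_to_coco(annotations), fh, indent=1)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for ann in annotations:
            tree = _to_voc(ann)
            tree.write(path / f"{ann.image_id}.xml")


# ---------------------------------------------------------------- COCO


def _read_coco(path: Path) -> list[ImageAnnotation]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
        images = {img["id"]: img for img in doc["images"]}
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise AnnotationParseError(f"{path}: not a COCO annotation file ({exc})") from exc

    anns: dict[object, ImageAnnotation] = {}
    for img_id, img in images.items():
        try:
            anns[img_id] = ImageAnnotation(
                image_id=str(img.get("file_name", img_id)).rsplit(".", 1)[0],
                width=int(img["width"]),
                height=int(img["height"]),
            )
        except (KeyError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: bad image record {img!r}") from exc

    for rec in doc.get("annotations", []):
        try:
            x, y, w, h = rec["bbox"]
            img_id = rec["image_id"]
        except (KeyError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: bad annotation record {rec!r}") from exc
        if img_id not in anns:
            raise AnnotationParseError(f"{path}: annotation references unknown image {img_id!r}")
        if w <= 0 or h <= 0:
            log.warning("%s: dropping zero-area box %r in image %r", path, rec["bbox"], img_id)
            continue
        anns[img_id].boxes.append(BoundingBox(x, y, x + w, y + h))
    return [anns[k] for k in sorted(anns, key=str)]


def _to_coco(annotations: list[ImageAnnotation]) -> dict:
    images, records = [], []
    ann_id = 1
    for i, ann in enumerate(annotations, start=1):
        images.append(
            {
                "id": i,
                "file_name": f"{ann.image_id}.png",
                "width": ann.width,
                "height": ann.height,
            }
        )
        for b in ann.boxes:
            records.append(
                {
                    "id": ann_id,
                    "image_id": i,
                    "category_id": 1,
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "area": b.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": records,
        "categories": [{"id": 1, "name": FRUIT_CLASS}],
    }


# ----------------------------------------------------------------- VOC


def _read_voc_file(path: Path) -> ImageAnnotation:
    try:
        root = ET.parse(path).getroot()
        size = root.find("size")
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
    except (ET.ParseError, TypeError, ValueError, AttributeError) as exc:
        raise AnnotationParseError(f"{path}: not a VOC annotation file ({exc})") from exc

    filename = root.findtext("filename") or path.stem
    ann = ImageAnnotation(
        image_id=filename.rsplit(".", 1)[0], width=width, height=height
    )
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationParseError(f"{path}: object without bndbox")
        try:
            xmin = float(bnd.findtext("xmin"))
            ymin = float(bnd.findtext("ymin"))
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: malformed bndbox in {path.stem}") from exc
        # VOC is 1-based inclusive; shift the min corner to 0-based half-open.
        box = (xmin - 1.0, ymin - 1.0, xmax, ymax)
        if box[2] <= box[0] or box[3] <= box[1]:
            log.warning("%s: dropping zero-area box %r", path, box)
            continue
        ann.boxes.append(BoundingBox(*box))
    return ann


def _to_voc(ann: ImageAnnotation) -> ET.ElementTree:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = FRUIT_CLASS
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = repr(b.x_min + 1.0)
        ET.SubElement(bnd, "ymin").text = repr(b.y_min + 1.0)
        ET.SubElement(bnd, "xmax").text = repr(b.x_max)
        ET.SubElement(bnd, "ymax").text = repr(b.y_max)
    return ET.ElementTree(root)
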