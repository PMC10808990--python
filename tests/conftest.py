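import numpy as np
import pytest

from fruitdet.geometry import BoundingBox, ImageAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_annotation(rng, width=128, height=128, max_boxes=6, min_size=4.0,
                      max_size=40.0, image_id="img"):
    """Random valid annotation with boxes fully inside the image."""
    n = int(rng.integers(0, max_boxes + 1))
    boxes = []
    for _ in range(n):
        w = rng.uniform(min_size, max_size)
        h = rng.uniform(min_size, max_size)
        x0 = rng.uniform(0, width - w)
        y0 = rng.uniform(0, height - h)
        boxes.append(BoundingBox(x0, y0, x0 + w, y0 + h))
    return ImageAnnotation(image_id, width, height, boxes)
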