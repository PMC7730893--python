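import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import label, regionprops


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def draw_ellipse_image(cy, cx, b, a, size=256, color=(90, 150, 70)):
    """Bright axis-aligned ellipse on black; returns (image, inclusive box)."""
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1
    img = np.zeros((size, size, 3), np.uint8)
    img[mask] = color
    return img, (cx - a, cy - b, cx + a, cy + b)


def baseline_classify(img: np.ndarray) -> str:
    """Independent pixel-statistics classifier for generated plum images.

    Uses only dark-area fraction, component count and component shape —
    no learning — so it serves as an oracle for class-conditional
    morphology of the synthetic data.
    """
    g = img.astype(float).mean(axis=2)
    fruit = ndimage.binary_fill_holes(g > 60)
    med = np.median(g[fruit])
    dark = fruit & (g < 0.68 * med)
    if dark.sum() / max(fruit.sum(), 1) < 0.003:
        return "normal"
    lab = label(dark, connectivity=2)
    props = [p for p in regionprops(lab) if p.area >= 4]
    if not props:
        return "normal"
    big = max(props, key=lambda p: p.area)
    if big.area / fruit.sum() >= 0.075:
        return "rot"
    if big.area >= 40 and (big.area / big.area_convex < 0.7
                           or big.axis_minor_length <= 4.5):
        return "crack"
    if len(props) >= 7:
        return "spot"
    return "scar"
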