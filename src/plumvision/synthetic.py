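"""Procedural generator of plum-like images with class-specific defects.

Each image shows a single ellipsoidal, green-toned fruit with radial shading
on a near-black background, emulating a ring-lit single-fruit photographing
rig.  Defect morphology is class-specific:

- rot:    one large irregular dark-brown region (>= 8% of the fruit area)
- scar:   one or two medium sharp-edged dark patches (2-6% each)
- crack:  one thin dark curvilinear polyline (width <= 3 px)
- spot:   many (10-40) small dark speckles (each <= 0.3% of the fruit)
- normal: clean skin

Every image is fully determined by (seed, class, index), so datasets are
reproducible byte for byte.  The generator makes no attempt at photorealism;
its purpose is that class identity is recoverable from pixel statistics, so
the whole downstream pipeline is testable without photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dataset import CLASS_ORDER, DefectClass

__all__ = ["GeneratorConfig", "generate_image", "generate_dataset"]


@dataclass
class ClassParams:
    """Defect morphology ranges for one class (areas are fruit fractions)."""

    blob_area: tuple[float, float] = (0.09, 0.16)    # rot
    patch_area: tuple[float, float] = (0.015, 0.04)  # scar
    patch_count: tuple[int, int] = (1, 2)
    crack_width: tuple[int, int] = (1, 3)
    crack_length: tuple[float, float] = (1.2, 1.8)   # in units of semi-axis a
    speckle_count: tuple[int, int] = (10, 40)
    speckle_radius: tuple[int, int] = (1, 3)
    defect_alpha: float = 0.85


@dataclass
class GeneratorConfig:
    image_size: int = 256
    background_level: int = 16
    noise_sigma: float = 2.5
    fruit_color: tuple[int, int, int] = (82, 142, 64)
    axis_range: tuple[float, float] = (0.28, 0.36)   # semi-axes / image size
    stem_probability: float = 0.0
    seed: int = 0
    class_params: ClassParams = field(default_factory=ClassParams)

    def __post_init__(self):
        if not 0.0 <= self.stem_probability <= 1.0:
            raise ValueError("stem_probability must lie in [0, 1]")
        lo, hi = self.axis_range
        if not (0 < lo < hi < 0.5):
            raise ValueError("axis_range must be non-degenerate and < 0.5")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


_DEFECT_COLOR = np.array([52.0, 38.0, 22.0])   # dark brown
_CRACK_COLOR = np.array([26.0, 19.0, 12.0])


def _rng_for(cfg: GeneratorConfig, cls: DefectClass, index: int):
    ci = CLASS_ORDER.index(cls)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, index]))


def _irregular_blob(rng, yy, xx, cy, cx, r0: float) -> np.ndarray:
    """Boolean mask of a radius-modulated blob centred at (cy, cx)."""
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    mod = np.ones_like(theta)
    for k in range(2, 5):
        mod += (rng.uniform(0.03, 0.09) * np.sin(k * theta + rng.uniform(0, 2 * np.pi)))
    return rad <= r0 * mod


def _paint(img: np.ndarray, mask: np.ndarray, color: np.ndarray,
           alpha: float) -> None:
    img[mask] = (1 - alpha) * img[mask] + alpha * color


def generate_image(cls: DefectClass, cfg: GeneratorConfig | None = None,
                   index: int = 0) -> tuple[np.ndarray, DefectClass]:
    """Render one (H, W, 3) uint8 image of the given class."""
    cfg = cfg or GeneratorConfig()
    rng = _rng_for(cfg, cls, index)
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    cy = s / 2 + rng.uniform(-s * 0.03, s * 0.03)
    cx = s / 2 + rng.uniform(-s * 0.03, s * 0.03)
    a = rng.uniform(*cfg.axis_range) * s       # horizontal semi-axis
    b = rng.uniform(*cfg.axis_range) * s       # vertical semi-axis
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    fruit = r2 <= 1.0

    img = np.full((s, s, 3), float(cfg.background_level))
    shade = 0.72 + 0.28 * np.sqrt(np.clip(1.0 - r2, 0.0, 1.0))
    tint = rng.normal(0.0, 5.0, size=3)
    base = np.clip(np.array(cfg.fruit_color, dtype=float) + tint, 0, 255)
    img[fruit] = base[None, :] * shade[fruit, None]

    fruit_area = float(fruit.sum())
    p = cfg.class_params

    def _inside_point(max_r=0.55):
        t = rng.uniform(0, 2 * np.pi)
        r = max_r * np.sqrt(rng.uniform(0, 1))
        return cy + r * b * np.sin(t), cx + r * a * np.cos(t)

    if cls is DefectClass.ROT:
        f = rng.uniform(*p.blob_area)
        r0 = np.sqrt(f * fruit_area / np.pi)
        dy, dx = _inside_point(0.45)
        mask = _irregular_blob(rng, yy, xx, dy, dx, r0) & fruit
        _paint(img, mask, _DEFECT_COLOR, p.defect_alpha)
    elif cls is DefectClass.SCAR:
        for _ in range(rng.integers(p.patch_count[0], p.patch_count[1] + 1)):
            f = rng.uniform(*p.patch_area)
            r0 = np.sqrt(f * fruit_area / np.pi)
            dy, dx = _inside_point(0.55)
            # sharp-edged patch: blob with mild modulation, full alpha edge
            mask = _irregular_blob(rng, yy, xx, dy, dx, r0) & fruit
            _paint(img, mask, _DEFECT_COLOR * 0.9, min(1.0, p.defect_alpha + 0.1))
    elif cls is DefectClass.CRACK:
        width = int(rng.integers(p.crack_width[0], p.crack_width[1] + 1))
        length = rng.uniform(*p.crack_length) * a
        dy, dx = _inside_point(0.3)
        ang = rng.uniform(0, 2 * np.pi)
        n_seg = 16
        step = length / n_seg
        mask = np.zeros((s, s), dtype=bool)
        py, px = dy, dx
        for _ in range(n_seg):
            ang += rng.normal(0.0, 0.3)
            qy, qx = py + step * np.sin(ang), px + step * np.cos(ang)
            # steer back toward the centre if the walk is about to leave
            if ((qx - cx) / a) ** 2 + ((qy - cy) / b) ** 2 > 0.72:
                ang = np.arctan2(cy - py, cx - px) + rng.normal(0.0, 0.3)
                qy, qx = py + step * np.sin(ang), px + step * np.cos(ang)
            npts = max(2, int(step * 2))
            ly = np.linspace(py, qy, npts)
            lx = np.linspace(px, qx, npts)
            for oy in range(-(width // 2), width - width // 2):
                for ox in range(-(width // 2), width - width // 2):
                    iy = np.clip(np.rint(ly + oy), 0, s - 1).astype(int)
                    ix = np.clip(np.rint(lx + ox), 0, s - 1).astype(int)
                    mask[iy, ix] = True
            py, px = qy, qx
        _paint(img, mask & fruit, _CRACK_COLOR, 0.95)
    elif cls is DefectClass.SPOT:
        n_spots = int(rng.integers(p.speckle_count[0], p.speckle_count[1] + 1))
        for _ in range(n_spots):
            rad = int(rng.integers(p.speckle_radius[0], p.speckle_radius[1] + 1))
            dy, dx = _inside_point(0.8)
            mask = (np.hypot(yy - dy, xx - dx) <= rad) & fruit
            _paint(img, mask, _DEFECT_COLOR, 0.7)

    if cfg.stem_probability > 0 and rng.uniform() < cfg.stem_probability:
        # short brown stub at the top of the fruit
        ty = cy - b
        mask = ((np.abs(xx - cx) <= 2)
                & (yy >= ty - 12) & (yy <= ty + 6))
        _paint(img, mask, np.array([92.0, 68.0, 40.0]), 0.9)

    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), cls


def generate_dataset(cfg: GeneratorConfig, counts: dict[str, int],
                     out_dir) -> pd.DataFrame:
    """Write PNGs in a directory-per-class layout plus a manifest CSV.

    Idempotent for a fixed config: rerunning rewrites identical bytes.
    Returns the manifest (path, label, source_id, augmentation_tag).
    """
    out = Path(out_dir)
    rows = []
    for name, n in counts.items():
        if n < 1:
            raise ValueError(f"count for class {name!r} must be >= 1")
        cls = DefectClass.from_name(name)
        cdir = out / name
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            img, _ = generate_image(cls, cfg, i)
            fname = f"{name}_{i:05d}.png"
            Image.fromarray(img).save(cdir / fname)
            rows.append({"path": str(Path(name) / fname), "label": name,
                         "source_id": f"{name}_{i:05d}",
                         "augmentation_tag": "orig"})
    df = pd.DataFrame(rows, columns=["path", "label", "source_id",
                                     "augmentation_tag"])
    df.to_csv(out / "manifest.csv", index=False)
    return df
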