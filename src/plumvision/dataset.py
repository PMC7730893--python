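"""Defect classes, severity-priority labeling, augmentation and splitting.

The five surface-condition classes carry a total severity order
rot > crack > scar > spot > normal: a fruit showing several defects is
labeled with the most severe one.  The canonical class order used for every
matrix and report is [rot, spot, scar, crack, normal].

Augmentation expands each image into exactly 10 variants: the identity, the
seven non-trivial 45-degree rotations, the horizontal mirror, and the
vertical mirror.  Axis-aligned members are exact pixel permutations; the
45-degree family resamples bilinearly with reflective padding so the output
stays square.

Splitting is performed on ORIGINAL images, before augmentation, so that no
augmented variant of a held-out original ever reaches the training side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

__all__ = ["DefectClass", "CLASS_ORDER", "CLASS_NAMES", "assign_label",
           "augment", "AUGMENTATION_TAGS", "SplitSpec", "split",
           "LabeledImage", "write_manifest", "read_manifest"]


class DefectClass(enum.Enum):
    """Surface-condition class with its severity rank (higher = worse)."""

    ROT = ("rot", 4)
    CRACK = ("crack", 3)
    SCAR = ("scar", 2)
    SPOT = ("spot", 1)
    NORMAL = ("normal", 0)

    def __init__(self, label: str, severity: int):
        self.label = label
        self.severity = severity

    @classmethod
    def from_name(cls, name: str) -> "DefectClass":
        for m in cls:
            if m.label == name:
                return m
        raise ValueError(f"unknown defect class {name!r}")


#: Canonical report/matrix order.
CLASS_ORDER = [DefectClass.ROT, DefectClass.SPOT, DefectClass.SCAR,
               DefectClass.CRACK, DefectClass.NORMAL]
CLASS_NAMES = [c.label for c in CLASS_ORDER]


def assign_label(defects_present) -> DefectClass:
    """Most severe member of a set of defect names; empty set -> normal."""
    members = {DefectClass.from_name(d) for d in defects_present}
    if DefectClass.NORMAL in members:
        raise ValueError("'normal' is not a defect; pass an empty set instead")
    if not members:
        return DefectClass.NORMAL
    return max(members, key=lambda m: m.severity)


# -- augmentation ------------------------------------------------------------

AUGMENTATION_TAGS = ["orig", "rot45", "rot90", "rot135", "rot180", "rot225",
                     "rot270", "rot315", "mirror", "mirror180"]


def _rotate(img: np.ndarray, angle: int) -> np.ndarray:
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(img, k=angle // 90))
    out = _sk_rotate(img.astype(np.float64), angle, resize=False, order=1,
                     mode="symmetric", preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(img: np.ndarray, scheme=None) -> list[tuple[str, np.ndarray]]:
    """The 10-variant expansion of one square image.

    ``scheme`` may replace the default list of (tag, transform) pairs; the
    first member must be the identity.
    """
    img = np.asarray(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"augmentation requires a square image, got {img.shape}")
    if scheme is None:
        scheme = ([("orig", lambda a: a.copy())]
                  + [(f"rot{d}", lambda a, d=d: _rotate(a, d))
                     for d in range(45, 360, 45)]
                  + [("mirror", lambda a: np.ascontiguousarray(a[:, ::-1])),
                     ("mirror180", lambda a: np.ascontiguousarray(a[::-1, :]))])
    return [(tag, fn(img)) for tag, fn in scheme]


# -- splitting ---------------------------------------------------------------

@dataclass
class SplitSpec:
    """4:1 (default) per-class split of original images.

    ``overrides`` maps class name -> (n_train, n_test) to reproduce reported
    counts that deviate from the exact ratio.
    """

    ratio: float = 0.8
    seed: int = 0
    overrides: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class LabeledImage:
    image: np.ndarray
    label: DefectClass
    source_id: str
    augmentation_tag: str = "orig"


def split(originals: dict[str, list], spec: SplitSpec | None = None,
          warn=None) -> tuple[dict[str, list], dict[str, list]]:
    """Seeded per-class shuffle then deterministic cut into train/test.

    ``originals`` maps class name -> list of items (ids or images).  The
    train side receives round(ratio * n) items.  Classes with fewer than 5
    originals trigger a warning callback and a degenerate split (all but one
    item to train).
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    train: dict[str, list] = {}
    test: dict[str, list] = {}
    for name in sorted(originals):
        items = list(originals[name])
        n = len(items)
        order = rng.permutation(n)
        if name in spec.overrides:
            n_train, n_test = spec.overrides[name]
            if n_train + n_test != n:
                raise ValueError(
                    f"override for {name!r} sums to {n_train + n_test}, "
                    f"but class has {n} originals")
        elif n < 5:
            if warn is not None:
                warn(f"class {name!r} has only {n} originals; degenerate split")
            n_train = max(n - 1, 0)
        else:
            n_train = int(round(spec.ratio * n))
        train[name] = [items[i] for i in order[:n_train]]
        test[name] = [items[i] for i in order[n_train:]]
    return train, test


# -- manifests ---------------------------------------------------------------

def write_manifest(rows: list[dict], path) -> pd.DataFrame:
    """CSV manifest with columns path,label,source_id,augmentation_tag."""
    df = pd.DataFrame(rows, columns=["path", "label", "source_id",
                                     "augmentation_tag"])
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["label"]) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"manifest contains unknown labels: {sorted(bad)}")
    return df
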