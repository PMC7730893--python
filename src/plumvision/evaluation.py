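"""Confusion-matrix construction and per-class precision/recall/F1.

Rows are true classes, columns predicted classes, both in the canonical
order [rot, spot, scar, crack, normal].  All metrics derive from integer
counts: recall_k = cm[k,k]/rowsum_k, precision_k = cm[k,k]/colsum_k (0 when
the column is empty), F1 the harmonic mean (0 when P + R = 0), and macro
averages are unweighted means over classes.

``reported_confusion`` returns the 5x5 count matrix of the original
green-plum defect network on its 2500-image test set, shipped as a versioned
CSV fixture; the per-class metrics computed from it are the package's exact
reproduction surface.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dataset import CLASS_NAMES, DefectClass

__all__ = ["build_confusion", "metrics_from_confusion",
           "misclassification_rate", "reported_confusion",
           "confusion_to_frame", "save_confusion", "load_confusion"]


def _class_index(label) -> int:
    if isinstance(label, DefectClass):
        return CLASS_NAMES.index(label.label)
    if isinstance(label, str):
        if label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {label!r}")
        return CLASS_NAMES.index(label)
    idx = int(label)
    if not 0 <= idx < len(CLASS_NAMES):
        raise ValueError(f"class index {idx} out of range")
    return idx


def build_confusion(true_labels, predicted_labels) -> np.ndarray:
    """5x5 count matrix; labels may be names, DefectClass members or indices."""
    t = [_class_index(v) for v in true_labels]
    p = [_class_index(v) for v in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    c = len(CLASS_NAMES)
    cm = np.zeros((c, c), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """Per-class recall/precision/F1 plus macro averages and micro accuracy."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    diag = np.diag(cm)
    recall = np.where(rows > 0, diag / np.maximum(rows, 1), 0.0)
    precision = np.where(cols > 0, diag / np.maximum(cols, 1), 0.0)
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return {
        "classes": list(CLASS_NAMES),
        "recall": recall.tolist(),
        "precision": precision.tolist(),
        "f1": f1.tolist(),
        "macro_recall": float(recall.mean()),
        "macro_precision": float(precision.mean()),
        "macro_f1": float(f1.mean()),
        "accuracy": float(diag.sum() / cm.sum()),
    }


def misclassification_rate(cm: np.ndarray, from_class, to_class) -> float:
    """Fraction of from_class's row predicted as to_class."""
    fi, ti = _class_index(from_class), _class_index(to_class)
    if fi == ti:
        raise ValueError("from_class and to_class must differ")
    row = cm[fi].sum()
    if row == 0:
        raise ValueError(f"row for {from_class!r} is empty")
    return float(cm[fi, ti] / row)


def reported_confusion() -> np.ndarray:
    """The published test-set confusion matrix (5x5, canonical class order).

    Loaded from the versioned CSV fixture shipped with the package.  Row
    sums are the augmented test counts (800, 800, 280, 160, 460); the trace
    is 2339 of 2500.
    """
    with resources.files("plumvision.data").joinpath(
            "reported_confusion.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    if list(df.index) != CLASS_NAMES or list(df.columns) != CLASS_NAMES:
        raise ValueError("fixture class order is corrupted")
    return df.to_numpy(dtype=np.int64)


def confusion_to_frame(cm: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(cm, index=CLASS_NAMES, columns=CLASS_NAMES)


def save_confusion(cm: np.ndarray, path) -> None:
    confusion_to_frame(cm).to_csv(path)


def load_confusion(path) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col=0)
    return df.to_numpy(dtype=np.int64)
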