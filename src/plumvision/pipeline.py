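"""End-to-end pipeline: generate -> preprocess -> split -> train -> evaluate.

Each stage is an importable function that reads the previous stage's
artifacts from disk and writes its own; rerunning a stage whose outputs
already exist is a no-op unless ``force`` is set.  Every artifact directory
carries a ``meta.json`` recording the configuration hash and seed that
produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from . import dataset as ds
from . import evaluation as ev
from .config import RunConfig, config_hash
from .model import NetworkSpec, load_checkpoint, predict, save_checkpoint
from .preprocess import PreprocessParams, preprocess_image
from .synthetic import GeneratorConfig, generate_dataset
from .training import SWAConfig, Standardizer, TrainConfig, train

__all__ = ["run_pipeline", "stage_generate", "stage_preprocess",
           "stage_split", "stage_train", "stage_evaluate", "load_split_arrays"]


def _write_meta(path: Path, cfg: RunConfig, stage: str) -> None:
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(json.dumps(
        {"stage": stage, "config_hash": config_hash(cfg), "seed": cfg.seed},
        indent=2))


def _done(path: Path, marker: str) -> bool:
    return (path / marker).exists()


def stage_generate(cfg: RunConfig, out: Path, force: bool = False) -> Path:
    raw = out / "raw"
    if not force and _done(raw, "manifest.csv"):
        return raw
    gcfg = GeneratorConfig(image_size=cfg.generator.image_size,
                           stem_probability=cfg.generator.stem_probability,
                           seed=cfg.seed)
    generate_dataset(gcfg, cfg.generator.counts, raw)
    _write_meta(raw, cfg, "generate")
    return raw


def stage_preprocess(cfg: RunConfig, out: Path, force: bool = False) -> Path:
    raw, proc = out / "raw", out / "processed"
    if not force and _done(proc, "manifest.csv"):
        return proc
    params = PreprocessParams(
        gaussian_kernel=cfg.preprocess.gaussian_kernel,
        block_size=cfg.preprocess.block_size, offset=cfg.preprocess.offset,
        canny_low=cfg.preprocess.canny_low, canny_high=cfg.preprocess.canny_high)
    manifest = pd.read_csv(raw / "manifest.csv")
    rows = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(raw / row["path"]).convert("RGB"))
        crop = preprocess_image(img, params)
        dest = proc / row["path"]
        dest.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(crop).save(dest)
        rows.append(dict(row))
    pd.DataFrame(rows).to_csv(proc / "manifest.csv", index=False)
    _write_meta(proc, cfg, "preprocess")
    return proc


def stage_split(cfg: RunConfig, out: Path, force: bool = False) -> Path:
    proc, spl = out / "processed", out / "split"
    if not force and _done(spl, "train_manifest.csv"):
        return spl
    manifest = pd.read_csv(proc / "manifest.csv")
    per_class = {name: grp.to_dict("records")
                 for name, grp in manifest.groupby("label")}
    spec = ds.SplitSpec(
        ratio=cfg.dataset.ratio, seed=cfg.seed,
        overrides={k: tuple(v) for k, v in cfg.dataset.overrides.items()})
    train_side, test_side = ds.split(per_class, spec)
    spl.mkdir(parents=True, exist_ok=True)

    def _expand(side: dict, do_augment: bool) -> pd.DataFrame:
        rows = []
        tags = ds.AUGMENTATION_TAGS if do_augment else ["orig"]
        for name in ds.CLASS_NAMES:
            for rec in side.get(name, []):
                for tag in tags:
                    rows.append({"path": rec["path"], "label": name,
                                 "source_id": rec["source_id"],
                                 "augmentation_tag": tag})
        return pd.DataFrame(rows, columns=["path", "label", "source_id",
                                           "augmentation_tag"])

    _expand(train_side, cfg.dataset.augment_train).to_csv(
        spl / "train_manifest.csv", index=False)
    _expand(test_side, cfg.dataset.augment_test).to_csv(
        spl / "test_manifest.csv", index=False)
    _write_meta(spl, cfg, "split")
    return spl


def load_split_arrays(out: Path, which: str,
                      resolution: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Materialise a split manifest into (N, 3, H, W) uint8 + label indices.

    Augmentation tags are applied on the fly; ``resolution`` optionally
    downscales each image (bilinear) before stacking.
    """
    proc = Path(out) / "processed"
    manifest = pd.read_csv(Path(out) / "split" / f"{which}_manifest.csv")
    images, labels = [], []
    # manifest rows for one source are contiguous: cache one image's variants
    cached_path, cached_variants = None, None
    for _, row in manifest.iterrows():
        if row["path"] != cached_path:
            base = np.asarray(Image.open(proc / row["path"]).convert("RGB"))
            cached_path, cached_variants = row["path"], dict(ds.augment(base))
        img = cached_variants[row["augmentation_tag"]]
        if resolution is not None and img.shape[0] != resolution:
            img = np.clip(np.rint(_sk_resize(
                img.astype(np.float64), (resolution, resolution), order=1,
                mode="edge", anti_aliasing=True, preserve_range=True)),
                0, 255).astype(np.uint8)
        images.append(img.transpose(2, 0, 1))
        labels.append(ds.CLASS_NAMES.index(row["label"]))
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def stage_train(cfg: RunConfig, out: Path, force: bool = False,
                log=None) -> Path:
    ckpt = out / "train" / "final.npz"
    if not force and ckpt.exists():
        return ckpt
    res = cfg.training.train_resolution
    images, labels = load_split_arrays(out, "train", resolution=res)
    tcfg = TrainConfig(
        batch_size=cfg.training.batch_size, base_lr=cfg.training.base_lr,
        weight_decay=cfg.training.weight_decay, momentum=cfg.training.momentum,
        epochs=cfg.training.epochs, loss=cfg.loss.name, gamma=cfg.loss.gamma,
        guard=cfg.loss.guard, seed=cfg.seed,
        swa=SWAConfig(enabled=cfg.swa.enabled, start_epoch=cfg.swa.start_epoch,
                      cycle_steps=cfg.swa.cycle_steps, alpha1=cfg.swa.alpha1,
                      alpha2=cfg.swa.alpha2, n_cycles=cfg.swa.n_cycles))
    spec = NetworkSpec(fc_units=cfg.model.fc_units,
                       pool_grid=tuple(cfg.model.pool_grid),
                       width_multiplier=cfg.model.width_multiplier)
    net, hist, st = train(tcfg, images, labels, spec=spec, log=log)
    ckpt.parent.mkdir(parents=True, exist_ok=True)
    save_checkpoint(net, ckpt, extra={
        "mean": st.mean.tolist(), "std": st.std.tolist(),
        "train_resolution": res, "config_hash": config_hash(cfg),
        "seed": cfg.seed})
    (ckpt.parent / "history.json").write_text(json.dumps(
        {"epoch_loss": hist.epoch_loss, "epoch_lr": hist.epoch_lr,
         "snapshots": hist.snapshots}, indent=2))
    _write_meta(ckpt.parent, cfg, "train")
    return ckpt


def evaluate_checkpoint(ckpt_path, images: np.ndarray, labels: np.ndarray,
                        batch_size: int = 64) -> tuple[np.ndarray, dict]:
    net, header = load_checkpoint(ckpt_path)
    st = Standardizer(np.asarray(header["extra"]["mean"], dtype=np.float32),
                      np.asarray(header["extra"]["std"], dtype=np.float32))
    preds = []
    for i in range(0, len(images), batch_size):
        idx, _ = predict(net, st(images[i: i + batch_size]))
        preds.append(idx)
    preds = np.concatenate(preds)
    cm = ev.build_confusion(labels.tolist(), preds.tolist())
    return cm, ev.metrics_from_confusion(cm)


def stage_evaluate(cfg: RunConfig, out: Path, force: bool = False) -> dict:
    edir = out / "eval"
    if not force and _done(edir, "metrics.json"):
        return json.loads((edir / "metrics.json").read_text())
    ckpt = out / "train" / "final.npz"
    if not ckpt.exists():
        raise FileNotFoundError(f"missing upstream artifact {ckpt}")
    images, labels = load_split_arrays(
        out, "test", resolution=cfg.training.train_resolution)
    cm, metrics = evaluate_checkpoint(ckpt, images, labels)
    edir.mkdir(parents=True, exist_ok=True)
    ev.save_confusion(cm, edir / "confusion.csv")
    metrics = {**metrics, "config_hash": config_hash(cfg), "seed": cfg.seed}
    (edir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    _write_meta(edir, cfg, "evaluate")
    return metrics


def run_pipeline(config: RunConfig | str | Path, out_dir,
                 force: bool = False, log=None) -> dict:
    """Run every stage in order; returns the final metrics dictionary."""
    if not isinstance(config, RunConfig):
        from .config import load_config
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in (stage_generate, stage_preprocess, stage_split):
        stage(config, out, force=force)
        if log is not None:
            log(f"stage {stage.__name__} done")
    stage_train(config, out, force=force, log=log)
    metrics = stage_evaluate(config, out, force=force)
    if log is not None:
        log(f"accuracy {metrics['accuracy']:.4f}")
    return metrics
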