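"""Training / evaluation / prediction pipeline over manifest datasets,
checkpoint serialization, and the four-variant ablation runner.

A checkpoint is a single ``.npz`` archive holding a version tag, the JSON
encoded ``ModelConfig``, and every parameter and buffer of the network.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import SwinStageConfig
from .data_io import load_image, load_pair, read_manifest, save_mask
from .losses import LossConfig, total_loss
from .metrics import METRIC_NAMES, aggregate, evaluate_pair
from .network import ABLATION_VARIANTS, BAFNet, ModelConfig
from .nn import SGD, Tensor, no_grad

__all__ = [
    "TrainConfig", "train", "evaluate", "predict", "run_ablation",
    "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = "bafnet-ckpt-1"


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the published settings
    (SGD, batch 4, 60 epochs of 350 batches, initial lr 0.01).  Momentum 0.9
    and zero weight decay are this package's documented defaults; the LR is
    held constant."""

    batch_size: int = 4
    epochs: int = 60
    iters_per_epoch: int = 350
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    alpha: float = 0.5
    seed: int = 0
    device: str = "cpu"
    image_size: int | None = None  # None: use images at native size

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.iters_per_epoch) < 1:
            raise ValueError("batch_size, epochs and iters_per_epoch must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


# ------------------------------------------------------------------ ckpt I/O
def save_checkpoint(model: BAFNet, path) -> None:
    cfg = dataclasses.asdict(model.cfg)
    cfg["swin"] = dataclasses.asdict(model.cfg.swin)
    meta = {"version": CHECKPOINT_VERSION, "config": cfg}
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> BAFNet:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        cfg_dict = meta["config"]
        swin = SwinStageConfig(**cfg_dict.pop("swin"))
        cfg = ModelConfig(swin=swin, **cfg_dict)
        model = BAFNet(cfg, seed=0)
        state = {k[len("state/"):]: archive[k] for k in archive.files
                 if k.startswith("state/")}
    model.load_state_dict(state)
    return model


# ----------------------------------------------------------------- data load
def _load_split(manifest: pd.DataFrame, split: str, image_size: int | None):
    rows = manifest[manifest["split"] == split]
    images, masks = [], []
    for _, row in rows.iterrows():
        img, msk = load_pair(row["image_path"], row["mask_path"], image_size)
        images.append(img)
        masks.append(msk)
    if not images:
        return None, None
    return np.stack(images), np.stack(masks).astype(np.float32)


def _resolve_manifest(data) -> pd.DataFrame:
    return data if isinstance(data, pd.DataFrame) else read_manifest(data)


# ------------------------------------------------------------------ training
def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data,
          out_dir) -> tuple[Path, list]:
    """Seeded SGD on the compound loss; saves the best-val-mIoU checkpoint.

    Returns (checkpoint path, history).  History is one record per epoch with
    train loss, validation loss and validation mIoU; it is also written as
    JSON lines next to the checkpoint.  An epoch is ``iters_per_epoch``
    batches resampled (with replacement across the epoch) from the training
    split, so small datasets still define an epoch.
    """
    manifest = _resolve_manifest(data)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, y = _load_split(manifest, "train", train_cfg.image_size)
    if X is None:
        raise ValueError("training split is empty")
    Xv, yv = _load_split(manifest, "val", train_cfg.image_size)

    rng = np.random.default_rng(train_cfg.seed)
    model = BAFNet(model_cfg, seed=train_cfg.seed)
    loss_cfg = LossConfig(alpha=train_cfg.alpha)
    opt = SGD(model.parameters(), lr=train_cfg.lr, momentum=train_cfg.momentum,
              weight_decay=train_cfg.weight_decay)
    history, best = [], (-1.0, None)
    ckpt_path = out / "checkpoint.npz"
    for epoch in range(train_cfg.epochs):
        model.train()
        losses = []
        for _ in range(train_cfg.iters_per_epoch):
            idx = rng.choice(len(X), size=min(train_cfg.batch_size, len(X)),
                             replace=False)
            loss = total_loss(model(Tensor(X[idx])), Tensor(y[idx]), loss_cfg)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss (epoch {epoch})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if Xv is not None:
            model.eval()
            val_losses, reports = [], []
            with no_grad():
                for i in range(len(Xv)):
                    pred = model(Tensor(Xv[i : i + 1]))
                    val_losses.append(
                        total_loss(pred, Tensor(yv[i : i + 1]), loss_cfg).item()
                    )
                    reports.append(evaluate_pair(pred.numpy()[0, 0], yv[i, 0]))
            record["val_loss"] = float(np.mean(val_losses))
            record["val_miou"] = aggregate(reports).IoU
            selector = record["val_miou"]
        else:
            selector = -record["train_loss"]
        history.append(record)
        if selector > best[0]:
            best = (selector, epoch)
            save_checkpoint(model, ckpt_path)
    if best[1] is None:
        save_checkpoint(model, ckpt_path)
    (out / "history.jsonl").write_text(
        "\n".join(json.dumps(r) for r in history) + "\n"
    )
    return ckpt_path, history


def evaluate(checkpoint, data, split: str = "test",
             image_size: int | None = None) -> pd.DataFrame:
    """Per-image metric table plus an aggregate row, percent scale."""
    model = checkpoint if isinstance(checkpoint, BAFNet) else load_checkpoint(checkpoint)
    manifest = _resolve_manifest(data)
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"split {split!r} is empty")
    model.eval()
    reports, ids = [], []
    with no_grad():
        for _, row in rows.iterrows():
            img, msk = load_pair(row["image_path"], row["mask_path"], image_size)
            pred = model(Tensor(img[None])).numpy()[0, 0]
            reports.append(evaluate_pair(pred, msk[0]))
            ids.append(row["id"])
    table = pd.DataFrame(
        [r.as_percent() for r in reports], index=ids, columns=list(METRIC_NAMES)
    )
    table.loc["mean"] = pd.Series(aggregate(reports).as_percent())
    return table.round(2)


def predict(checkpoint, image_path, out_mask_path,
            image_size: int | None = None) -> np.ndarray:
    """Segment one image and write the thresholded {0,1} mask PNG."""
    model = checkpoint if isinstance(checkpoint, BAFNet) else load_checkpoint(checkpoint)
    model.eval()
    img = load_image(image_path, image_size)
    with no_grad():
        proba = model(Tensor(img[None])).numpy()[0, 0]
    mask = (proba >= 0.5).astype(np.uint8)
    save_mask(mask, out_mask_path)
    return mask


def run_ablation(data, train_cfg: TrainConfig, base_channels: int = 32,
                 image_size: int = 512, out_dir=None,
                 window_size: int = 8) -> pd.DataFrame:
    """Train the four nested variants under identical seeds and data order.

    Emits one row per variant with its component flags, parameter count and
    test-split metrics (percent scale).
    """
    manifest = _resolve_manifest(data)
    out = Path(out_dir) if out_dir is not None else None
    records = []
    for name, (use_msff, use_fsff, use_baf) in ABLATION_VARIANTS.items():
        cfg = ModelConfig(
            base_channels=base_channels, image_size=image_size,
            use_msff=use_msff, use_fsff=use_fsff, use_baf=use_baf,
            swin=SwinStageConfig(window_size=window_size),
        )
        run_dir = (out / name) if out is not None else Path(".") / "scratch" / name
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ckpt, _ = train(cfg, train_cfg, manifest, run_dir)
        model = load_checkpoint(ckpt)
        split = "test" if (manifest["split"] == "test").any() else "train"
        table = evaluate(model, manifest, split=split,
                         image_size=train_cfg.image_size)
        row = {"model": name, "MSFF": use_msff, "FSFF": use_fsff, "BAF": use_baf,
               "n_params": model.num_parameters()}
        row.update(table.loc["mean"].to_dict())
        records.append(row)
    return pd.DataFrame(records)
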