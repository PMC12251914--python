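"""Seeded SGD training loop with the linear learning-rate decay schedule.

The schedule follows the two-parameter convention: the rate starts at
``lr0`` and decays linearly over the epoch budget to ``lr0 * lrf`` (e.g.
0.01 * 0.01 = 1e-4).  Momentum-SGD with decoupled weight decay updates every
learnable array; each epoch logs the three loss terms and, when a
validation split is given, precision/recall/mAP@0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .dataset import AnnotatedImage, read_yolo_labels
from .loss import detection_loss
from .metrics import evaluate, precision_recall_f1, ConfusionCounts
from .network import Model, build_variant, decode_predictions, nms

__all__ = ["TrainConfig", "train", "evaluate_model", "load_split"]


@dataclass
class TrainConfig:
    input_size: int = 640
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch: int = 16
    epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lrf < 1.0:
            raise ValueError("lrf must lie in (0, 1)")

    def lr_at(self, epoch: int) -> float:
        """Linear decay from lr0 to lr0*lrf across the epoch budget."""
        if self.epochs <= 1:
            return self.lr0 * self.lrf
        frac = epoch / (self.epochs - 1)
        return self.lr0 * (1.0 - frac * (1.0 - self.lrf))


@dataclass
class EpochLog:
    epoch: int
    lr: float
    box_loss: float
    cls_loss: float
    dfl_loss: float
    val_p: float = float("nan")
    val_r: float = float("nan")
    val_map50: float = float("nan")


class SGD:
    def __init__(self, params, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= lr * g
            p.data += v


def _resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels
    return np.asarray(Image.fromarray(pixels).resize((size, size), Image.BILINEAR))


def load_split(root, split: str) -> list:
    """Read an images/{split} + labels/{split} directory into memory."""
    from PIL import Image

    root = Path(root)
    img_dir, lab_dir = root / "images" / split, root / "labels" / split
    if not img_dir.is_dir():
        raise FileNotFoundError(f"missing split directory {img_dir}")
    items = []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        boxes = read_yolo_labels(lab_dir / f"{img_path.stem}.txt")
        items.append(AnnotatedImage(np.asarray(Image.open(img_path).convert("RGB")),
                                    boxes, img_path.stem))
    if not items:
        raise ValueError(f"split {split!r} is empty")
    return items


def _to_batch(items, size: int) -> Tensor:
    arr = np.stack([_resize_image(im.pixels, size).transpose(2, 0, 1)
                    for im in items]).astype(np.float32) / 255.0
    return Tensor(arr)


def evaluate_model(model: Model, items, input_size: int,
                   conf_thr: float = 0.01, iou_thr: float = 0.5):
    """mAP@0.5 plus micro-averaged P/R of a model over a list of images."""
    model.eval()
    preds_all, gts_all = [], []
    with ag.no_grad():
        for im in items:
            x = _to_batch([im], input_size)
            raw = model(x)
            dets = nms(decode_predictions(model, raw, input_size, conf_thr),
                       0.45, conf_thr)
            preds_all.append(dets)
            gts_all.append(im.boxes)
    report = evaluate(preds_all, gts_all, iou_thr)
    agg = ConfusionCounts()
    for preds, gts in zip(preds_all, gts_all):
        from .metrics import match_detections
        for cc in match_detections(preds, gts, iou_thr).values():
            agg.tp += cc.tp
            agg.fp += cc.fp
            agg.fn += cc.fn
    p, r, _ = precision_recall_f1(agg)
    return report.map50, p, r, report


def train(variant, train_items, config: TrainConfig, val_items=None,
          log_path=None, num_classes: int = 24, verbose: bool = False):
    """Train a variant (name or built model) on in-memory annotated images.

    Returns (model, list-of-EpochLog).  The loop is fully seeded: the same
    configuration and data reproduce the loss curve exactly.
    """
    if isinstance(variant, Model):
        model = variant
    else:
        model = build_variant(variant, num_classes=num_classes, seed=config.seed)
    if not train_items:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), config.momentum, config.weight_decay)
    size = config.input_size
    logs: list[EpochLog] = []
    lines = ["epoch\tlr\tbox\tcls\tdfl\tval_P\tval_R\tval_mAP50"]
    for epoch in range(config.epochs):
        model.train()
        lr = config.lr_at(epoch)
        order = rng.permutation(len(train_items))
        sums = np.zeros(3)
        nb = 0
        for s in range(0, len(order), config.batch):
            batch = [train_items[i] for i in order[s:s + config.batch]]
            x = _to_batch(batch, size)
            preds = model(x)
            box_l, cls_l, dfl_l = detection_loss(preds, [b.boxes for b in batch], size)
            total = box_l + cls_l + dfl_l
            model.zero_grad()
            total.backward()
            opt.step(lr)
            sums += [box_l.item(), cls_l.item(), dfl_l.item()]
            nb += 1
        log = EpochLog(epoch + 1, lr, *(sums / max(nb, 1)))
        if val_items:
            log.val_map50, log.val_p, log.val_r, _ = evaluate_model(
                model, val_items, size)
        logs.append(log)
        lines.append(f"{log.epoch}\t{lr:.6f}\t{log.box_loss:.4f}\t{log.cls_loss:.4f}"
                     f"\t{log.dfl_loss:.4f}\t{log.val_p:.4f}\t{log.val_r:.4f}"
                     f"\t{log.val_map50:.4f}")
        if verbose:
            print(lines[-1], flush=True)
    if log_path is not None:
        Path(log_path).write_text("\n".join(lines) + "\n")
    return model, logs
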