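"""Three-term anchor-free detection loss: complete-IoU box regression,
binary cross-entropy classification, and a distribution focal term over the
discretised box-edge distances.

Assignment uses a centre prior: every ground-truth box claims the grid cell
containing its centre at each of the three scales (strides 8/16/32), giving
each object a positive anchor per scale.  The classification target is the
one-hot identity at positive anchors and zero elsewhere; box and
distribution terms are evaluated at positive anchors only.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["detection_loss", "assign_targets", "ciou"]

BOX_GAIN, CLS_GAIN, DFL_GAIN = 7.5, 0.5, 1.5


def assign_targets(batch_boxes, grid_hw, stride, img_size, reg_max=16):
    """Positive anchors for one scale.

    Returns (img_idx, cell_idx, ltrb_targets, class_ids); distances are in
    cell units, clamped into the representable range [0, reg_max - 1.01].
    """
    gh, gw = grid_hw
    imgs, cells, ltrb, cls = [], [], [], []
    for n, boxes in enumerate(batch_boxes):
        for b in boxes:
            cx, cy = b.cx * img_size / stride, b.cy * img_size / stride
            bw, bh = b.w * img_size / stride, b.h * img_size / stride
            j, i = min(gw - 1, int(cx)), min(gh - 1, int(cy))
            ax, ay = j + 0.5, i + 0.5
            d = (ax - (cx - bw / 2), ay - (cy - bh / 2),
                 (cx + bw / 2) - ax, (cy + bh / 2) - ay)
            if min(d) <= 0:          # centre cell outside the box: skip scale
                continue
            d = tuple(min(reg_max - 1.01, v) for v in d)
            imgs.append(n)
            cells.append(i * gw + j)
            ltrb.append(d)
            cls.append(b.class_id)
    return (np.asarray(imgs, dtype=np.int64), np.asarray(cells, dtype=np.int64),
            np.asarray(ltrb, dtype=np.float32), np.asarray(cls, dtype=np.int64))


def _log_softmax(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def ciou(pred_xyxy, tgt_xyxy, eps: float = 1e-7) -> Tensor:
    """Complete IoU between parallel (P,) tensors of box coordinates."""
    px1, py1, px2, py2 = pred_xyxy
    tx1, ty1, tx2, ty2 = tgt_xyxy
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clamp(lo=0.0) * ih.clamp(lo=0.0)
    pa = (px2 - px1) * (py2 - py1)
    ta = (tx2 - tx1) * (ty2 - ty1)
    union = pa + ta - inter + eps
    iou = inter / union
    # enclosing box diagonal
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (((px1 + px2) - (tx1 + tx2)) ** 2 + ((py1 + py2) - (ty1 + ty2)) ** 2) * 0.25
    v = ((tx2 - tx1) / (ty2 - ty1 + eps)).atan() - ((px2 - px1) / (py2 - py1 + eps)).atan()
    v = v * v * (4.0 / math.pi ** 2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))   # detached
    return iou - rho2 / c2 - alpha * v


def detection_loss(preds, batch_boxes, img_size: int, reg_max: int = 16):
    """(box_loss, cls_loss, dfl_loss) for one batch.

    ``preds`` is the head output: per-scale (box_logits, cls_logits) with
    shapes (N, 4*reg_max, H, W) and (N, nc, H, W); ``batch_boxes`` a list of
    per-image normalised ground-truth boxes.
    """
    strides = (8, 16, 32)
    bins = np.arange(reg_max, dtype=np.float32)
    n_pos_total = 0
    box_terms, dfl_terms, cls_terms = [], [], []
    for (box_logit, cls_logit), stride in zip(preds, strides):
        n, c4, gh, gw = box_logit.shape
        nc = cls_logit.shape[1]
        hw = gh * gw
        imgs, cells, ltrb, cls_ids = assign_targets(
            batch_boxes, (gh, gw), stride, img_size, reg_max)
        # classification target over the full map
        tcls = np.zeros((n, hw, nc), dtype=np.float32)
        if len(imgs):
            tcls[imgs, cells, cls_ids] = 1.0
        cls_flat = cls_logit.reshape(n, nc, hw).transpose(0, 2, 1)
        cls_terms.append(cls_flat.bce_with_logits(tcls).sum())
        if len(imgs) == 0:
            continue
        n_pos_total += len(imgs)
        box_flat = box_logit.reshape(n, c4, hw).transpose(0, 2, 1)
        pos = box_flat[(imgs, cells)]                  # (P, 4*reg_max)
        pos = pos.reshape(len(imgs), 4, reg_max)
        logp = _log_softmax(pos)
        # distribution focal: two-bin interpolated cross-entropy
        t = ltrb
        li = np.floor(t).astype(np.int64)
        li1 = np.minimum(li + 1, reg_max - 1)
        wl = (li + 1).astype(np.float32) - t
        wr = t - li.astype(np.float32)
        pidx = np.arange(len(imgs))[:, None].repeat(4, axis=1)
        sidx = np.arange(4)[None, :].repeat(len(imgs), axis=0)
        nll = -(Tensor(wl) * logp[(pidx, sidx, li)] +
                Tensor(wr) * logp[(pidx, sidx, li1)])
        dfl_terms.append(nll.sum())
        # decoded expectation -> CIoU against the target distances
        prob = pos.softmax(axis=-1)
        d = (prob * Tensor(bins[None, None, :])).sum(axis=-1)   # (P, 4) ltrb
        ax = (cells % gw).astype(np.float32) + 0.5
        ay = (cells // gw).astype(np.float32) + 0.5
        pred = (Tensor(ax) - d[:, 0], Tensor(ay) - d[:, 1],
                Tensor(ax) + d[:, 2], Tensor(ay) + d[:, 3])
        tgt = (Tensor(ax - ltrb[:, 0]), Tensor(ay - ltrb[:, 1]),
               Tensor(ax + ltrb[:, 2]), Tensor(ay + ltrb[:, 3]))
        box_terms.append((1.0 - ciou(pred, tgt)).sum())
    denom = max(n_pos_total, 1)
    zero = Tensor(np.zeros(()))
    box_loss = (sum(box_terms[1:], box_terms[0]) if box_terms else zero) * (BOX_GAIN / denom)
    cls_loss = sum(cls_terms[1:], cls_terms[0]) * (CLS_GAIN / denom)
    dfl_loss = (sum(dfl_terms[1:], dfl_terms[0]) if dfl_terms else zero) * (DFL_GAIN / (4 * denom))
    return box_loss, cls_loss, dfl_loss
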