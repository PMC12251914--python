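"""Detector graph assembly and the named variant registry.

The baseline is the "n"-scale YOLOv11 configuration (depth multiple 0.50,
width multiple 0.25): a convolutional backbone with four cross-stage C3k2
stages, an SPPF pooling block and a C2PSA attention block, a top-down /
bottom-up neck with nearest upsampling and concatenation, and an anchor-free
decoupled head at strides 8/16/32.

Variants substitute blocks at fixed graph positions (0-based layer indices):

===========  ==========================================================
name         substitutions
===========  ==========================================================
I-pos1       Inception-F for the stride-2 backbone convs at 3, 5, 7
I-pos2       Inception-F for the neck C3k2 blocks at 16 and 22
I            both of the above
F-pos1       C2f-Faster for the backbone C3k2 blocks at 2 and 4
F / F-pos2   C2f-Faster for the neck C3k2 blocks at 13 and 19
S            SPPELANF for the SPPF block at 9
C            CBAM for the C2PSA block at 10
IF/IFS/IFSC  unions of I, F, S, C
===========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from . import nn
from .autodiff import Tensor

__all__ = ["VariantSpec", "Detection", "Model", "build_variant", "forward_detect",
           "nms", "VARIANTS", "BASE_LAYERS"]


# (from, kind, kwargs); from=-1 means previous layer.  Widths follow the
# n-scale multiples (0.25 x yaml widths, capped at 256).
BASE_LAYERS = [
    (-1, "conv", dict(c2=16, k=3, s=2)),        # 0  P1/2
    (-1, "conv", dict(c2=32, k=3, s=2)),        # 1  P2/4
    (-1, "c3k2", dict(c2=64, c3k=False, e=0.25)),   # 2
    (-1, "conv", dict(c2=64, k=3, s=2)),        # 3  P3/8
    (-1, "c3k2", dict(c2=128, c3k=False, e=0.25)),  # 4
    (-1, "conv", dict(c2=128, k=3, s=2)),       # 5  P4/16
    (-1, "c3k2", dict(c2=128, c3k=True)),       # 6
    (-1, "conv", dict(c2=256, k=3, s=2)),       # 7  P5/32
    (-1, "c3k2", dict(c2=256, c3k=True)),       # 8
    (-1, "sppf", dict(c2=256)),                 # 9
    (-1, "c2psa", dict(c2=256)),                # 10
    (-1, "upsample", {}),                       # 11
    ([-1, 6], "concat", {}),                    # 12
    (-1, "c3k2", dict(c2=128, c3k=False)),      # 13
    (-1, "upsample", {}),                       # 14
    ([-1, 4], "concat", {}),                    # 15
    (-1, "c3k2", dict(c2=64, c3k=False)),       # 16  P3 out
    (-1, "conv", dict(c2=64, k=3, s=2)),        # 17
    ([-1, 13], "concat", {}),                   # 18
    (-1, "c3k2", dict(c2=128, c3k=False)),      # 19  P4 out
    (-1, "conv", dict(c2=128, k=3, s=2)),       # 20
    ([-1, 10], "concat", {}),                   # 21
    (-1, "c3k2", dict(c2=256, c3k=True)),       # 22  P5 out
    ([16, 19, 22], "detect", {}),               # 23
]

# Inception-F projection/group widths per placement.  Backbone placements use
# strongly grouped pointwise projections (the block is meant to be nearly
# parameter-free there); the deeper neck placements retain denser channel
# mixing after feature concatenation.
INCF_SITES = {
    3: dict(stride=2, pw_groups=32, r3_groups=32),
    5: dict(stride=2, pw_groups=32, r3_groups=32),
    7: dict(stride=2, pw_groups=32, r3_groups=32),
    16: dict(stride=1, pw_groups=2, r3_groups=2),
    22: dict(stride=1, pw_groups=2, r3_groups=4),
}

_SUB_I1 = {i: ("incf", dict(variant="F", **INCF_SITES[i])) for i in (3, 5, 7)}
_SUB_I2 = {i: ("incf", dict(variant="F", **INCF_SITES[i])) for i in (16, 22)}
_SUB_F2 = {i: ("c2f_faster", {}) for i in (13, 19)}
_SUB_F1 = {i: ("c2f_faster", {}) for i in (2, 4)}
_SUB_S = {9: ("sppelanf", {})}
_SUB_C = {10: ("cbam", {})}


def _merge(*subs):
    out = {}
    for s in subs:
        out.update(s)
    return out


@dataclass(frozen=True)
class VariantSpec:
    """Declarative description of one network configuration."""
    name: str
    substitutions: dict = field(default_factory=dict)


def _incf_variant(tag):
    return {i: ("incf", dict(variant=tag, **INCF_SITES[i])) for i in (3, 5, 7)}


VARIANTS = {
    "baseline": {},
    "I-pos1": _SUB_I1,
    "I-pos2": _SUB_I2,
    "I": _merge(_SUB_I1, _SUB_I2),
    "F-pos1": _SUB_F1,
    "F-pos2": _SUB_F2,
    "F": _SUB_F2,
    "F-pos1+2": _merge(_SUB_F1, _SUB_F2),
    "S": _SUB_S,
    "C": _SUB_C,
    "IF": _merge(_SUB_I1, _SUB_I2, _SUB_F2),
    "IFS": _merge(_SUB_I1, _SUB_I2, _SUB_F2, _SUB_S),
    "IFSC": _merge(_SUB_I1, _SUB_I2, _SUB_F2, _SUB_S, _SUB_C),
    "inceptionA": _incf_variant("A"),
    "inceptionB": _incf_variant("B"),
    "inceptionF": _incf_variant("F"),
    "sppelan": {9: ("sppelan", {})},
}


@dataclass
class Detection:
    """One decoded detection: normalised centre-format box + class + score."""
    class_id: int
    box: tuple  # (cx, cy, w, h) in [0, 1]
    confidence: float

    def xyxy(self):
        cx, cy, w, h = self.box
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    @property
    def area(self):
        return self.box[2] * self.box[3]


class Model(nn.Module):
    """A built detector: ordered layer list plus routing metadata."""

    def __init__(self, spec: VariantSpec, num_classes: int = 24, seed: int = 0):
        super().__init__()
        self.spec = spec
        self.num_classes = num_classes
        rng = np.random.default_rng(seed)
        self.routes = []       # per-layer 'from'
        self.kinds = []
        self.widths = []
        layers = []
        ch = [3]               # running channel widths; ch[i+1] = layer i out

        for idx, (frm, kind, kw) in enumerate(BASE_LAYERS):
            if idx in spec.substitutions:
                kind, skw = spec.substitutions[idx]
                kw = dict(kw, **skw)
            if isinstance(frm, int):
                c1 = ch[-1] if frm == -1 else ch[frm + 1]
            else:
                c1 = sum(ch[-1] if f == -1 else ch[f + 1] for f in frm)
            if kind == "detect":
                kw = dict(kw, _ch=tuple(ch[f + 1] for f in frm))
            c2 = kw.get("c2", c1)
            mod, c2 = self._build_layer(kind, c1, c2, kw, rng)
            layers.append(mod)
            self.routes.append(frm)
            self.kinds.append(kind)
            self.widths.append(c2)
            ch.append(c2)
        self.layers = nn.ModuleList(layers)
        object.__setattr__(self, "head", layers[-1])  # alias, not re-registered

    def _build_layer(self, kind, c1, c2, kw, rng):
        if kind == "conv":
            return nn.Conv(c1, c2, kw.get("k", 1), kw.get("s", 1), rng=rng), c2
        if kind == "c3k2":
            return nn.C3k2(c1, c2, n=1, c3k=kw.get("c3k", False),
                           e=kw.get("e", 0.5), rng=rng), c2
        if kind == "sppf":
            return nn.SPPF(c1, c2, rng=rng), c2
        if kind == "c2psa":
            return nn.C2PSA(c1, c2, n=1, rng=rng), c2
        if kind == "upsample":
            return nn.Upsample(), c1
        if kind == "concat":
            return nn.Concat(), c1
        if kind == "incf":
            return nn.InceptionF(c1, c2, variant=kw.get("variant", "F"),
                                 stride=kw.get("stride", 1),
                                 pw_groups=kw.get("pw_groups", 16),
                                 r3_groups=kw.get("r3_groups", 16), rng=rng), c2
        if kind == "c2f_faster":
            return nn.C2fFaster(c1, c2, n=1, e=kw.get("e", 0.5), rng=rng), c2
        if kind == "sppelanf":
            return nn.SPPELANF(c1, c2, rng=rng), c2
        if kind == "sppelan":
            return nn.SPPELAN(c1, c2, rng=rng), c2
        if kind == "cbam":
            return nn.CBAM(c1, rng=rng), c1
        if kind == "detect":
            ch = kw["_ch"]
            return nn.Detect(self.num_classes, ch=ch, rng=rng), 0
        raise ValueError(f"unknown block kind {kind!r}")

    def forward(self, x: Tensor):
        """Run the graph; returns the head's per-scale (box, cls) logits."""
        outs: list = []
        y = x
        for i, (frm, mod) in enumerate(zip(self.routes, self.layers)):
            if isinstance(frm, int):
                inp = y if frm == -1 else outs[frm]
                if self.kinds[i] == "detect":
                    raise RuntimeError("detect layer needs multiple inputs")
                y = mod(inp)
            else:
                feats = [y if f == -1 else outs[f] for f in frm]
                y = mod(feats) if self.kinds[i] != "detect" else mod(feats)
            outs.append(y)
        return y


def build_variant(name_or_spec, num_classes: int = 24, seed: int = 0) -> Model:
    """Instantiate a registry variant (or an explicit :class:`VariantSpec`)."""
    if isinstance(name_or_spec, VariantSpec):
        spec = name_or_spec
    else:
        if name_or_spec not in VARIANTS:
            raise KeyError(f"unknown variant {name_or_spec!r}; "
                           f"known: {sorted(VARIANTS)}")
        spec = VariantSpec(name_or_spec, VARIANTS[name_or_spec])
    for idx in spec.substitutions:
        if not 0 <= idx < len(BASE_LAYERS) - 1:
            raise KeyError(f"substitution index {idx} not in graph")
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    return Model(spec, num_classes=num_classes, seed=seed)


# ---------------------------------------------------------------------------
# decoding and non-maximum suppression
# ---------------------------------------------------------------------------


def decode_predictions(model: Model, preds, img_size: int,
                       conf_thr: float = 0.25):
    """Distribution-to-box expectation + sigmoid class scores.

    Returns a list of raw Detections (before NMS) for batch element 0.
    """
    reg_max = model.head.reg_max
    bins = np.arange(reg_max, dtype=np.float32)
    dets: list[Detection] = []
    for (box_logit, cls_logit), stride in zip(preds, model.head.strides):
        b = box_logit.data[0]          # (4*reg_max, H, W)
        c = cls_logit.data[0]          # (nc, H, W)
        _, h, w = b.shape
        d = b.reshape(4, reg_max, h, w)
        d = d - d.max(axis=1, keepdims=True)
        e = np.exp(d)
        p = e / e.sum(axis=1, keepdims=True)
        dist = (p * bins[None, :, None, None]).sum(axis=1)   # (4, H, W) l,t,r,b
        prob = 1.0 / (1.0 + np.exp(-np.clip(c, -60.0, 60.0)))
        xs = (np.arange(w) + 0.5)[None, :]
        ys = (np.arange(h) + 0.5)[:, None]
        x1 = (xs - dist[0]) * stride
        y1 = (ys - dist[1]) * stride
        x2 = (xs + dist[2]) * stride
        y2 = (ys + dist[3]) * stride
        conf = prob.max(axis=0)
        cls = prob.argmax(axis=0)
        keep = conf >= conf_thr
        for i, j in zip(*np.nonzero(keep)):
            a1, b1 = max(0.0, x1[i, j]) / img_size, max(0.0, y1[i, j]) / img_size
            a2, b2 = min(float(img_size), x2[i, j]) / img_size, min(float(img_size), y2[i, j]) / img_size
            if a2 <= a1 or b2 <= b1:
                continue
            dets.append(Detection(int(cls[i, j]),
                                  (float(a1 + a2) / 2, float(b1 + b2) / 2,
                                   float(a2 - a1), float(b2 - b1)),
                                  float(conf[i, j])))
    return dets


def box_iou(a, b) -> float:
    """IoU of two xyxy boxes."""
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def nms(dets: list[Detection], iou_thr: float = 0.45,
        conf_thr: float = 0.25) -> list[Detection]:
    """Greedy class-wise suppression, deterministic tie-breaking."""
    if not 0.0 <= iou_thr <= 1.0 or not 0.0 <= conf_thr <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    cand = [(d, i) for i, d in enumerate(dets) if d.confidence >= conf_thr]
    cand.sort(key=lambda t: (-t[0].confidence, -t[0].area, t[1]))
    kept: list[Detection] = []
    by_class: dict[int, list] = {}
    for d, _ in cand:
        boxes = by_class.setdefault(d.class_id, [])
        if all(box_iou(d.xyxy(), k) < iou_thr for k in boxes):
            boxes.append(d.xyxy())
            kept.append(d)
    return kept


def forward_detect(model: Model, image: np.ndarray, conf_thr: float = 0.25,
                   iou_thr: float = 0.45) -> list[Detection]:
    """Full inference on one image (H, W, 3) uint8 or (3, H, W) float."""
    if image.ndim == 3 and image.shape[2] == 3:
        x = image.transpose(2, 0, 1).astype(np.float32) / 255.0
    else:
        x = image.astype(np.float32)
    _, h, w = x.shape
    if h % 32 or w % 32 or h != w:
        raise ValueError(f"image side must be square and divisible by 32, got {h}x{w}")
    model.eval()
    with ag.no_grad():
        preds = model(Tensor(x[None]))
    dets = decode_predictions(model, preds, h, conf_thr)
    return nms(dets, iou_thr, conf_thr)
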