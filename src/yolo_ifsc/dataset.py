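"""Dataset construction pipeline: YOLO-format annotation I/O, SSIM redundancy
filtering, stratified splitting and the three annotation-aware augmentation
strategies (rotation with box re-derivation, salt-and-pepper noise, gamma +
HSV-brightness jitter).

Boxes use the YOLO txt convention: one ``class cx cy w h`` line per object,
centre-format coordinates normalised to [0, 1], image origin top-left.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import color as _skcolor
from skimage import transform as _sktransform
from skimage.metrics import structural_similarity

__all__ = [
    "BBox", "AnnotatedImage", "AugmentationConfig", "SplitManifest",
    "read_yolo_labels", "write_yolo_labels", "ssim_filter",
    "rotate_with_boxes", "add_salt_pepper", "gamma_hsv_jitter",
    "stratified_split", "augment_training_set", "save_dataset", "write_data_yaml",
]

NUM_IDENTITIES = 24


@dataclass(frozen=True)
class BBox:
    """Normalised centre-format bounding box with an identity class."""
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.class_id < NUM_IDENTITIES:
            raise ValueError(f"class_id {self.class_id} outside 0..{NUM_IDENTITIES - 1}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError("box centre outside the unit square")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError("box size must lie in (0, 1]")

    def xyxy(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @staticmethod
    def from_xyxy(class_id, x1, y1, x2, y2) -> "BBox":
        return BBox(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass
class AnnotatedImage:
    """An RGB uint8 image with its normalised box annotations."""
    pixels: np.ndarray          # (H, W, 3) uint8
    boxes: list                 # list[BBox]
    source_id: str = ""

    @property
    def height(self):
        return self.pixels.shape[0]

    @property
    def width(self):
        return self.pixels.shape[1]


@dataclass
class AugmentationConfig:
    """Ranges of the three augmentation strategies."""
    rotation_range: tuple = (-45.0, 45.0)      # degrees
    sp_density_range: tuple = (0.005, 0.03)    # salt-and-pepper pixel fraction
    gamma_range: tuple = (0.5, 1.5)
    hsv_v_range: tuple = (0.8, 1.2)            # +-20 % brightness scale
    seed: int = 0


@dataclass
class SplitManifest:
    test: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    training: list = field(default_factory=list)
    instance_counts: dict = field(default_factory=dict)

    def splits(self):
        return {"test": self.test, "val": self.validation, "train": self.training}


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_yolo_labels(path) -> list:
    """Parse a YOLO txt label file into a list of boxes.

    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            try:
                boxes.append(BBox(cid, *vals))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return boxes


def write_yolo_labels(boxes, path) -> None:
    """Write boxes as ``class cx cy w h`` lines, 6 decimal places."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")


# ---------------------------------------------------------------------------
# redundancy filtering
# ---------------------------------------------------------------------------


def frame_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Windowed SSIM between two frames, computed on grayscale."""
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    ga = _skcolor.rgb2gray(a) if a.ndim == 3 else a.astype(np.float64) / 255.0
    gb = _skcolor.rgb2gray(b) if b.ndim == 3 else b.astype(np.float64) / 255.0
    return float(structural_similarity(ga, gb, data_range=1.0))


def ssim_filter(frames, threshold: float = 0.65):
    """Drop consecutive near-duplicate frames.

    The first frame is always retained; each subsequent frame is kept only if
    its SSIM against the last *retained* frame falls below the threshold
    (high similarity means redundant).  Returns the retained indices.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    kept = [0]
    for i in range(1, len(frames)):
        s = frame_ssim(frames[i], frames[kept[-1]])
        if s < threshold:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# augmentation strategies
# ---------------------------------------------------------------------------


def _rotate_point(x, y, cx, cy, theta):
    """Rotate (x, y) about (cx, cy); positive theta is counter-clockwise in
    conventional axes, which appears clockwise with the image's y-down axis."""
    dx, dy = x - cx, y - cy
    return (cx + dx * math.cos(theta) + dy * math.sin(theta),
            cy - dx * math.sin(theta) + dy * math.cos(theta))


def rotate_with_boxes(img: AnnotatedImage, angle_deg: float,
                      min_area_frac: float = 0.2) -> AnnotatedImage:
    """Rotate image about its centre; replace each box by the axis-aligned
    hull of its rotated corners, clipped to the image.  Boxes whose clipped
    area drops below ``min_area_frac`` of the original are dropped."""
    if not -180.0 <= angle_deg <= 180.0:
        raise ValueError("angle outside [-180, 180]")
    if angle_deg == 0.0:
        return replace(img, boxes=list(img.boxes))
    h, w = img.pixels.shape[:2]
    rot = _sktransform.rotate(img.pixels, angle_deg, resize=False,
                              preserve_range=True, order=1, mode="constant",
                              cval=114.0).astype(np.uint8)
    theta = math.radians(angle_deg)
    cx_img, cy_img = (w - 1) / 2.0, (h - 1) / 2.0
    new_boxes = []
    for b in img.boxes:
        x1, y1, x2, y2 = b.xyxy()
        corners = [(x1 * w, y1 * h), (x2 * w, y1 * h), (x2 * w, y2 * h), (x1 * w, y2 * h)]
        pts = [_rotate_point(px, py, cx_img, cy_img, theta) for px, py in corners]
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        nx1, ny1 = max(0.0, min(xs)), max(0.0, min(ys))
        nx2, ny2 = min(float(w), max(xs)), min(float(h), max(ys))
        if nx2 <= nx1 or ny2 <= ny1:
            continue
        orig_area = (x2 - x1) * w * (y2 - y1) * h
        if (nx2 - nx1) * (ny2 - ny1) < min_area_frac * orig_area:
            continue
        new_boxes.append(BBox.from_xyxy(b.class_id, nx1 / w, ny1 / h, nx2 / w, ny2 / h))
    return AnnotatedImage(rot, new_boxes, img.source_id)


def add_salt_pepper(img: AnnotatedImage, density: float,
                    rng: np.random.Generator) -> AnnotatedImage:
    """Set exactly round(density*H*W) pixels (without replacement) to black
    or white with equal probability.  Annotations are reused unchanged."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    h, w = img.pixels.shape[:2]
    n = int(round(density * h * w))
    out = img.pixels.copy()
    if n:
        flat = rng.choice(h * w, size=n, replace=False)
        vals = rng.integers(0, 2, size=n).astype(np.uint8) * 255
        out.reshape(-1, 3)[flat] = vals[:, None]
    return AnnotatedImage(out, list(img.boxes), img.source_id)


def gamma_hsv_jitter(img: AnnotatedImage, gamma: float,
                     v_scale: float) -> AnnotatedImage:
    """Power-law gamma correction followed by HSV value-channel scaling."""
    if not 0.5 <= gamma <= 1.5:
        raise ValueError("gamma outside [0.5, 1.5]")
    if not 0.8 <= v_scale <= 1.2:
        raise ValueError("v_scale outside [0.8, 1.2]")
    x = img.pixels.astype(np.float64) / 255.0
    x = x ** gamma
    hsv = _skcolor.rgb2hsv(x)
    hsv[..., 2] = np.clip(hsv[..., 2] * v_scale, 0.0, 1.0)
    out = np.clip(_skcolor.hsv2rgb(hsv) * 255.0, 0, 255).round().astype(np.uint8)
    return AnnotatedImage(out, list(img.boxes), img.source_id)


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------


def _allocate(counts: dict, total: int) -> dict:
    """Largest-remainder proportional allocation of ``total`` over strata."""
    n = sum(counts.values())
    raw = {k: total * v / n for k, v in counts.items()}
    alloc = {k: int(math.floor(r)) for k, r in raw.items()}
    leftover = total - sum(alloc.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - alloc[k]), k)):
        if leftover <= 0:
            break
        alloc[k] += 1
        leftover -= 1
    return alloc


def stratified_split(image_ids, strata_fn, sizes, seed: int = 0,
                     instance_counts=None) -> SplitManifest:
    """Draw test then validation sets by proportional stratified sampling;
    the remainder is the training set.

    ``sizes`` is (test_size, validation_size).  Within each stratum the
    allocation uses largest-remainder rounding; a stratum smaller than its
    allocation shrinks it with a warning.
    """
    image_ids = list(image_ids)
    test_size, val_size = sizes
    if test_size + val_size > len(image_ids):
        raise ValueError("split sizes exceed the number of images")
    rng = np.random.default_rng(seed)
    remaining = list(image_ids)
    picked = []
    for want in (test_size, val_size):
        strata: dict = {}
        for iid in remaining:
            strata.setdefault(strata_fn(iid), []).append(iid)
        alloc = _allocate({k: len(v) for k, v in strata.items()}, want)
        chosen = []
        for key in sorted(strata, key=str):
            members, take = strata[key], alloc.get(key, 0)
            if take > len(members):
                warnings.warn(f"stratum {key!r} smaller than its allocation "
                              f"({len(members)} < {take}); shrinking")
                take = len(members)
            idx = rng.choice(len(members), size=take, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
        picked.append(chosen)
        chosen_set = set(chosen)
        remaining = [i for i in remaining if i not in chosen_set]
    counts = instance_counts or {}
    manifest = SplitManifest(test=picked[0], validation=picked[1], training=remaining)
    for name, ids in manifest.splits().items():
        manifest.instance_counts[name] = sum(counts.get(i, 0) for i in ids)
    return manifest


# ---------------------------------------------------------------------------
# augmentation driver
# ---------------------------------------------------------------------------


def augment_training_set(images, config: AugmentationConfig, n_derived: int):
    """Generate exactly ``n_derived`` augmented images from the sources.

    Sources are cycled in a seeded random order; each derivative applies one
    strategy drawn uniformly from {rotation, salt-and-pepper, gamma+HSV}.
    Rotation re-derives the box coordinates; the other two reuse the source
    annotations verbatim.  Returns (derived_images, manifest_rows).
    """
    images = list(images)
    if not images:
        raise ValueError("no source images")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(images))
    derived, rows = [], []
    i = 0
    while len(derived) < n_derived:
        if i == len(order):
            order = rng.permutation(len(images))
            i = 0
        src = images[order[i]]
        i += 1
        strat = rng.integers(0, 3)
        if strat == 0:
            ang = rng.uniform(*config.rotation_range)
            out = rotate_with_boxes(src, float(ang))
            if not out.boxes:       # rotation clipped away every box; redraw
                continue
            tag = f"rot{ang:+.1f}"
        elif strat == 1:
            dens = rng.uniform(*config.sp_density_range)
            out = add_salt_pepper(src, float(dens), rng)
            tag = f"sp{dens:.3f}"
        else:
            gam = rng.uniform(*config.gamma_range)
            vs = rng.uniform(*config.hsv_v_range)
            out = gamma_hsv_jitter(src, float(gam), float(vs))
            tag = f"gm{gam:.2f}v{vs:.2f}"
        out.source_id = f"{src.source_id}_aug{len(derived):04d}_{tag}"
        derived.append(out)
        rows.append((src.source_id, out.source_id, tag, len(out.boxes)))
    return derived, rows


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def save_dataset(root, split_name: str, images) -> None:
    """Write images/<split> PNGs and labels/<split> txts with matching stems."""
    from PIL import Image

    root = Path(root)
    img_dir = root / "images" / split_name
    lab_dir = root / "labels" / split_name
    img_dir.mkdir(parents=True, exist_ok=True)
    lab_dir.mkdir(parents=True, exist_ok=True)
    for im in images:
        stem = im.source_id
        Image.fromarray(im.pixels).save(img_dir / f"{stem}.png")
        write_yolo_labels(im.boxes, lab_dir / f"{stem}.txt")


def write_data_yaml(root, path_name: str = "data.yaml") -> Path:
    """Dataset config naming the 24 identity classes and split directories."""
    import yaml

    root = Path(root)
    cfg = {
        "path": str(root),
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
        "names": {i: f"broiler_{i:02d}" for i in range(NUM_IDENTITIES)},
    }
    out = root / path_name
    with open(out, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out
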