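"""Synthetic flock scenes with ground-truth identities and a progressive
occlusion protocol.

Real cage recordings of the 24 tagged broilers are not redistributable, so
every pipeline stage is exercised on generated scenes instead: a textured
background, 2--6 "birds" drawn as ellipse clusters whose face region carries
two eye dots and a coloured 2x2 tag glyph uniquely encoding the identity
(echoing the coloured neck tags used in the real flock), tight face bounding
boxes, controllable mutual overlap, and rectangular occluders at three
severity levels placed inside the annotated face boxes.

Everything is driven by explicit seeds; the same spec always yields a
bit-identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import (AnnotatedImage, BBox, NUM_IDENTITIES, save_dataset,
                      write_data_yaml)

__all__ = ["SceneSpec", "OcclusionSpec", "OcclusionResult", "generate_scene",
           "generate_dataset", "synthesize_occlusion", "TAG_PALETTE"]

# 8-colour palette for the 2x2 tag glyph: 8^2 = 64 > 24 usable codes using
# the two top cells; the bottom cells carry a fixed white/black anchor pair
# that makes the glyph orientation unambiguous.
TAG_PALETTE = np.array([
    (230, 40, 40), (40, 160, 230), (40, 200, 80), (240, 200, 40),
    (180, 60, 220), (250, 130, 30), (60, 230, 220), (240, 120, 180),
], dtype=np.uint8)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""
    n_birds: int
    identity_ids: tuple
    image_size: int = 640
    overlap_level: float = 0.15   # maximum pairwise face-box IoU allowed
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_birds <= 6:
            raise ValueError("a scene holds between 2 and 6 birds")
        ids = tuple(self.identity_ids)
        if len(ids) != self.n_birds or len(set(ids)) != self.n_birds:
            raise ValueError("identity_ids must be n_birds distinct ids")
        if any(not 0 <= i < NUM_IDENTITIES for i in ids):
            raise ValueError("identity ids must lie in 0..23")


@dataclass(frozen=True)
class OcclusionSpec:
    """One of the three progressive occlusion severity levels.

    Level 1: coverage <= 10 % of the box, confined to the periocular zone
    (upper third), zero overflow.  Level 2: coverage 20 % +- 3 %, spanning the
    eye and lateral cheek band, horizontal overflow past the box allowed
    (capped at half the box width).  Level 3: coverage 50 % +- 5 % over the
    central region, with at most 5 % of the occluder area outside the box.
    """
    level: int

    BANDS = {1: (0.0, 0.10), 2: (0.17, 0.23), 3: (0.45, 0.55)}

    def __post_init__(self):
        if self.level not in self.BANDS:
            raise ValueError("occlusion level must be 1, 2 or 3")

    @property
    def band(self):
        return self.BANDS[self.level]


@dataclass
class OcclusionResult:
    image: AnnotatedImage
    covered_fraction: float
    occluder_xyxy: tuple
    overflow_fraction: float


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency brown/grey litter texture plus pixel noise."""
    coarse = rng.uniform(0.35, 0.65, size=(size // 16 + 1, size // 16 + 1))
    ys = np.linspace(0, coarse.shape[0] - 1, size)
    xs = np.linspace(0, coarse.shape[1] - 1, size)
    yi, xi = np.floor(ys).astype(int), np.floor(xs).astype(int)
    base = coarse[yi][:, xi]
    noise = rng.normal(0, 0.03, size=(size, size))
    v = np.clip(base + noise, 0, 1)
    img = np.stack([v * 150 + 40, v * 130 + 35, v * 100 + 30], axis=-1)
    return img.astype(np.uint8)


def _fill_ellipse(img, cx, cy, rx, ry, color):
    h, w = img.shape[:2]
    y0, y1 = max(0, int(cy - ry)), min(h, int(cy + ry) + 1)
    x0, x1 = max(0, int(cx - rx)), min(w, int(cx + rx) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    img[y0:y1, x0:x1][mask] = color


def _draw_bird(img, cx, cy, face_r, identity, rng):
    """Body + face ellipses, eyes, comb and the identity tag glyph.

    Returns the tight face bounding box (x1, y1, x2, y2) in pixels.
    """
    body_shade = rng.integers(200, 240)
    body_color = np.array([body_shade, body_shade, body_shade - 10], dtype=np.uint8)
    face_color = np.array([min(255, body_shade + 10)] * 3, dtype=np.uint8)
    # body below/behind the face
    _fill_ellipse(img, cx + face_r * 0.3, cy + face_r * 1.6,
                  face_r * 1.8, face_r * 1.3, body_color)
    # face disc
    _fill_ellipse(img, cx, cy, face_r, face_r * 1.05, face_color)
    # comb
    _fill_ellipse(img, cx, cy - face_r * 0.9, face_r * 0.35, face_r * 0.25,
                  np.array([200, 50, 50], dtype=np.uint8))
    # eyes in the upper third of the face
    eye_dy = -face_r * 0.35
    for sx in (-0.4, 0.4):
        _fill_ellipse(img, cx + sx * face_r, cy + eye_dy,
                      face_r * 0.12, face_r * 0.12, np.array([20, 20, 20], np.uint8))
    # beak
    _fill_ellipse(img, cx, cy + face_r * 0.25, face_r * 0.18, face_r * 0.12,
                  np.array([230, 180, 60], np.uint8))
    # identity tag glyph: 2x2 cell block under the beak (the "neck tag")
    a, b = divmod(int(identity), len(TAG_PALETTE))
    cell = max(2, int(face_r * 0.28))
    gx, gy = int(cx - cell), int(cy + face_r * 0.55)
    h, w = img.shape[:2]
    cells = [TAG_PALETTE[a], TAG_PALETTE[b],
             np.array([255, 255, 255], np.uint8), np.array([0, 0, 0], np.uint8)]
    for ci, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        y0, x0 = gy + dy * cell, gx + dx * cell
        img[max(0, y0):min(h, y0 + cell), max(0, x0):min(w, x0 + cell)] = cells[ci]
    x1 = cx - face_r
    y1 = cy - face_r * 1.15            # include the comb
    x2 = cx + face_r
    y2 = gy + 2 * cell                 # include the tag glyph
    return (x1, y1, x2, y2)


def _iou(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def generate_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one seeded scene; raises if the overlap budget cannot be met."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(size, rng)
    placed = []
    boxes = []
    order = sorted(spec.identity_ids)
    for identity in order:
        ok = False
        for _ in range(200):
            face_r = rng.uniform(0.055, 0.085) * size
            cx = rng.uniform(face_r * 1.3, size - face_r * 1.3)
            cy = rng.uniform(face_r * 1.6, size - face_r * 2.4)
            cand = (cx - face_r, cy - face_r * 1.15, cx + face_r, cy + face_r * 1.4)
            if all(_iou(cand, p) <= spec.overlap_level for p in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {spec.n_birds} birds within the overlap budget")
        bb = _draw_bird(img, cx, cy, face_r, identity, rng)
        placed.append(bb)
        x1, y1, x2, y2 = bb
        boxes.append(BBox.from_xyxy(identity,
                                    max(0.0, x1 / size), max(0.0, y1 / size),
                                    min(1.0, x2 / size), min(1.0, y2 / size)))
    # cage-like occluding bars in front of part of the scene
    if rng.uniform() < 0.5:
        for bx in range(int(rng.integers(2, 5))):
            x = int(rng.uniform(0, size - 4))
            img[:, x:x + 3] = (img[:, x:x + 3] * 0.35).astype(np.uint8)
    return AnnotatedImage(img, boxes, f"scene_{spec.seed:06d}")


def generate_dataset(n_images: int, split_sizes=(20, 20), seed: int = 0,
                     out_dir=None, image_size: int = 640):
    """Generate a full corpus with every identity present in every split.

    ``split_sizes`` gives (test, val); the remaining images are training.
    Returns the per-split lists of :class:`AnnotatedImage`; when ``out_dir``
    is given the standard images/{split} + labels/{split} + data.yaml layout
    is written as well.
    """
    test_n, val_n = split_sizes
    if n_images < test_n + val_n:
        raise ValueError("n_images smaller than the requested splits")
    rng = np.random.default_rng(seed)
    sizes = {"test": test_n, "val": val_n, "train": n_images - test_n - val_n}
    splits: dict = {}
    scene_seed = seed * 100003 % (2 ** 31)
    for name, count in sizes.items():
        images = []
        # identity coverage: cycle all 24 ids through the scenes of the split
        pool = []
        while len(pool) < count * 6:
            pool.extend(rng.permutation(NUM_IDENTITIES).tolist())
        cursor = 0
        for k in range(count):
            n_birds = int(rng.integers(2, 7))
            ids = []
            while len(ids) < n_birds:
                cand = pool[cursor % len(pool)]
                cursor += 1
                if cand not in ids:
                    ids.append(cand)
            spec = SceneSpec(n_birds, tuple(ids), image_size=image_size,
                             seed=(scene_seed + cursor * 977 + k) % (2 ** 31))
            img = generate_scene(spec)
            img.source_id = f"{name}_{k:05d}"
            images.append(img)
        splits[name] = images
    if out_dir is not None:
        out_dir = Path(out_dir)
        for name, images in splits.items():
            save_dataset(out_dir, name, images)
        write_data_yaml(out_dir)
    return splits


# ---------------------------------------------------------------------------
# progressive occlusion synthesis
# ---------------------------------------------------------------------------

OCCLUDER_COLOR = np.array([40, 40, 40], dtype=np.uint8)   # dark cage-bar grey


def _box_pixels(box: BBox, w: int, h: int):
    x1, y1, x2, y2 = box.xyxy()
    return (int(round(x1 * w)), int(round(y1 * h)),
            int(round(x2 * w)), int(round(y2 * h)))


def synthesize_occlusion(img: AnnotatedImage, box_index: int,
                         spec: OcclusionSpec, seed: int = 0) -> OcclusionResult:
    """Place one rectangular occluder over the selected face box.

    The achieved coverage (pixel-counted intersection over box area) is
    guaranteed to lie inside the level's band; labels are left unchanged so
    the identity ground truth is preserved.
    """
    if not 0 <= box_index < len(img.boxes):
        raise IndexError("box_index out of range")
    rng = np.random.default_rng(seed)
    h, w = img.pixels.shape[:2]
    bx1, by1, bx2, by2 = _box_pixels(img.boxes[box_index], w, h)
    bw, bh = bx2 - bx1, by2 - by1
    if bw <= 3 or bh <= 3:
        raise ValueError("box too small for the requested occlusion level")
    area = bw * bh
    lo, hi = spec.band
    target = rng.uniform(max(lo, hi * 0.7) if spec.level == 1 else lo, hi)

    if spec.level == 1:
        # periocular zone: upper third of the box, fully inside
        zone_h = max(1, bh // 3)
        side_len = (target * area) ** 0.5
        rh = max(1, min(zone_h, int(round(side_len))))
        rw = max(1, min(bw, int(round(target * area / rh))))
        # shrink until under the 10 % cap
        while rw * rh > hi * area and rw > 1:
            rw -= 1
        x0 = bx1 + int(rng.integers(0, max(1, bw - rw + 1)))
        y0 = by1 + int(rng.integers(0, max(1, zone_h - rh + 1)))
        rx1, ry1, rx2, ry2 = x0, y0, x0 + rw, y0 + rh
    elif spec.level == 2:
        # eye + lateral cheek band; may run horizontally past the box edge
        zone_y0, zone_h = by1, max(2, int(round(bh * 0.45)))
        rh = int(rng.integers(max(1, zone_h // 2), zone_h + 1))
        rw_in = max(1, int(round(target * area / rh)))
        rw_in = min(rw_in, bw)
        rh = max(1, min(zone_h, int(round(target * area / rw_in))))
        overflow = int(rng.integers(0, bw // 2 + 1))      # capped at w/2
        side = rng.integers(0, 2)
        if side == 0:
            rx1, rx2 = bx1 - overflow, bx1 + rw_in
        else:
            rx1, rx2 = bx2 - rw_in, bx2 + overflow
        y0 = zone_y0 + int(rng.integers(0, max(1, zone_h - rh + 1)))
        ry1, ry2 = y0, y0 + rh
    else:
        # central region, at most 5 % of the occluder outside the box
        rh = max(2, int(round(bh * 0.75)))
        rw = max(2, int(round(target * area / rh)))
        if rw > bw:
            rw = bw
            rh = max(2, int(round(target * area / rw)))
        cx, cy = (bx1 + bx2) // 2, (by1 + by2) // 2
        rx1, ry1 = cx - rw // 2, cy - rh // 2
        rx2, ry2 = rx1 + rw, ry1 + rh
        rx1, ry1 = max(rx1, bx1), max(ry1, by1)
        rx2, ry2 = min(rx2, bx2), min(ry2, by2)

    # exact pixel accounting, with a corrective trim/grow loop on width
    def coverage(r):
        x1, y1, x2, y2 = r
        ix1, iy1 = max(x1, bx1), max(y1, by1)
        ix2, iy2 = min(x2, bx2), min(y2, by2)
        inter = max(0, ix2 - ix1) * max(0, iy2 - iy1)
        occ = max(0, x2 - x1) * max(0, y2 - y1)
        return inter / area, (occ - inter) / occ if occ else 0.0

    rect = [rx1, ry1, rx2, ry2]
    for _ in range(4 * (bw + bh)):
        cov, _ov = coverage(rect)
        if lo <= cov <= hi:
            break
        if cov > hi:
            if rect[2] - rect[0] > 1:
                rect[2] -= 1
            else:
                rect[3] -= 1
        else:
            if rect[2] - rect[0] < bw and rect[2] < bx2:
                rect[2] += 1
            elif rect[3] - rect[1] < bh and rect[3] < by2:
                rect[3] += 1
            else:
                rect[0] = max(bx1, rect[0] - 1)
                rect[1] = max(by1, rect[1] - 1)
    cov, ov = coverage(rect)
    if not lo <= cov <= hi:
        raise ValueError(f"cannot reach level-{spec.level} coverage on this box")
    out = img.pixels.copy()
    x1, y1, x2, y2 = (max(0, rect[0]), max(0, rect[1]),
                      min(w, rect[2]), min(h, rect[3]))
    out[y1:y2, x1:x2] = OCCLUDER_COLOR
    return OcclusionResult(AnnotatedImage(out, list(img.boxes), img.source_id),
                           cov, tuple(rect), ov)
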