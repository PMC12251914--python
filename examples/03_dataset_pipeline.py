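"""Run the dataset-construction pipeline on synthetic material.

Mirrors the corpus construction protocol: SSIM redundancy filtering of
near-duplicate frames, a stratified test/validation/training split of 839
items into 108/216/515, and annotation-aware augmentation producing exactly
241 derived training images.
"""

import numpy as np

from yolo_ifsc.dataset import (AnnotatedImage, AugmentationConfig, BBox,
                               augment_training_set, ssim_filter,
                               stratified_split)

# redundancy filtering: 8 frames, of which consecutive pairs are duplicates
rng = np.random.default_rng(0)
base = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
frames = []
for k in range(4):
    frame = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
    frames += [frame, frame.copy()]
kept = ssim_filter(frames, threshold=0.65)
print(f"SSIM filter: kept {len(kept)} of {len(frames)} frames -> indices {kept}")

# stratified split: 839 ids over 6 strata
ids = [f"g{i % 6}_{i:04d}" for i in range(839)]
manifest = stratified_split(ids, lambda s: s.split("_")[0], (108, 216), seed=1)
print(f"split sizes: test={len(manifest.test)} val={len(manifest.validation)} "
      f"train={len(manifest.training)}")

# augmentation: 241 derivatives from the 515 training images
sources = [AnnotatedImage(rng.integers(0, 255, (48, 48, 3)).astype(np.uint8),
                          [BBox(i % 24, 0.5, 0.5, 0.5, 0.4)], f"src{i:04d}")
           for i in range(len(manifest.training))]
derived, rows = augment_training_set(sources, AugmentationConfig(seed=42), 241)
by_tag = {}
for _, _, tag, _ in rows:
    by_tag[tag[:2]] = by_tag.get(tag[:2], 0) + 1
print(f"augmentation: {len(derived)} derivatives "
      f"(rotation={by_tag.get('ro', 0)}, noise={by_tag.get('sp', 0)}, "
      f"gamma/HSV={by_tag.get('gm', 0)})")
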