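"""Train the IFSC variant on a small synthetic corpus and evaluate it.

A short CPU run (10 epochs, 40 images at 128x128) demonstrating the full
loop: loss terms fall epoch over epoch, the learning rate decays linearly
towards lr0*lrf, and validation mAP@0.5 is computed from decoded, NMS-
filtered detections.  Expect the three loss columns to drop steadily; at
this tiny scale mAP typically remains at zero -- the longer smoke run in
the test suite (120 images, 30 epochs) is where it becomes non-zero.
"""

from yolo_ifsc.synthetic import generate_dataset
from yolo_ifsc.train import TrainConfig, evaluate_model, train

splits = generate_dataset(40, (8, 8), seed=3, image_size=128)
cfg = TrainConfig(input_size=128, epochs=10, batch=8, seed=3)
model, logs = train("IFSC", splits["train"], cfg, val_items=splits["val"],
                    verbose=True)
map50, p, r, _ = evaluate_model(model, splits["test"], 128)
print(f"\ntest split: mAP@0.5={map50:.4f}  P={p:.4f}  R={r:.4f}")
print(f"final learning rate: {cfg.lr_at(cfg.epochs - 1):.6f} (= lr0 * lrf)")
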