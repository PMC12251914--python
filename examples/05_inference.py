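"""Run single-image inference with an (untrained) detector.

Shows the full decode path: multi-scale head outputs, distribution-to-box
expectation, confidence filtering and class-wise NMS.  With random weights
the detections are arbitrary, but every box is guaranteed to lie inside the
unit square with a valid confidence -- the decode contract downstream code
relies on.
"""

from yolo_ifsc.network import build_variant, forward_detect
from yolo_ifsc.synthetic import SceneSpec, generate_scene

scene = generate_scene(SceneSpec(3, (0, 8, 16), image_size=640, seed=5))
model = build_variant("IFSC", num_classes=24, seed=0)
dets = forward_detect(model, scene.pixels, conf_thr=0.01)
print(f"{len(dets)} detections above confidence 0.01 (untrained weights)")
for d in dets[:5]:
    print(f"  id {d.class_id:2d}  conf {d.confidence:.3f}  box {tuple(round(v, 3) for v in d.box)}")
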