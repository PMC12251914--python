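# yolo-ifsc

A pure-numpy implementation of **YOLO-IFSC**, a lightweight one-stage
detector family for non-contact identification of individual broiler
chickens by their faces in dense cage environments. Each of the 24 birds in
a flock is one class; the detector must cope with small facial regions,
heavy mutual occlusion and multi-target scenes, while staying small enough
for embedded deployment.

The architecture starts from the YOLOv11n baseline (n-scale: depth multiple
0.50, width multiple 0.25; anchor-free decoupled head at strides 8/16/32)
and substitutes four bespoke blocks:

- **Inception-F** — five parallel paths R1–R5 (dilated depthwise 3×3,
  dilated depthwise 5×5, grouped pointwise, max pooling, average pooling)
  fused by learned softmax weights: w = softmax(w′), y = Σᵢ wᵢ ⊙ x̂ᵢ.
  Ablation variants A (R1–R3) and B (R1–R4) are also provided.
- **C2f-Faster** — a C2f shell whose bottleneck opens with a *partial
  convolution* (PConv): a 3×3 conv over the first ⌈P·C⌉ channels (P = 1/4),
  identity on the rest, costing the fraction P of a full convolution
  (FLOPs = K_h·K_w·C_in·C_out·H·W·P), followed by two 1×1 convs and a
  residual connection.
- **SPPELANF** — a pyramid pooling block: 1×1 CBS projection to an
  intermediate width c\*, three chained 5×5/s1/p2 max pools, per-stage 1×1
  alignment convs, channel concatenation to 4c\* and a final 1×1 projection.
- **CBAM** — channel attention M_C = σ(MLP(AvgPool F) + MLP(MaxPool F))
  followed by spatial attention M_S = σ(f⁷ˣ⁷[AvgPool; MaxPool]), each gate
  multiplied into the feature map.

Because no deep-learning framework is assumed, the package ships its own
compact reverse-mode autodiff engine (`yolo_ifsc.autodiff`) with im2col/GEMM
convolutions, so all blocks are trainable on a CPU. Alongside the network
the package implements the surrounding study pipeline: YOLO-txt annotation
I/O, SSIM redundancy filtering (threshold 0.65), stratified splitting,
three annotation-aware augmentation strategies, a synthetic flock-scene
generator with a three-level progressive occlusion protocol, detection
metrics (greedy IoU matching, envelope AP, mAP@0.5), the CIoU + BCE + DFL
loss and a seeded SGD training loop.

## Worked example

```bash
python examples/01_profile_variants.py
```

prints the exact learnable-parameter counts and 640×640 FLOPs of the
variant ladder:

```
variant       params      M         FLOPs     G
baseline     2594504   2.59    6447078400   6.4
I-pos1       2139351   2.14    5357747200   5.4
I            2018049   2.02    5519129600   5.5
F-pos2       2533576   2.53    6296140800   6.3
S            2451784   2.45    6329568000   6.3
C            2353339   2.35    6186786368   6.2
IF           1957121   1.96    5368192000   5.4
IFS          1814401   1.81    5250681600   5.3
IFSC         1573236   1.57    4990389568   5.0

IFSC vs baseline: 39.4% fewer parameters, 22.6% fewer FLOPs
```

Reading the table: `I-pos1` places Inception-F in the backbone only, `I`
adds the two neck placements, `F-pos2` swaps the two mid-neck feature
blocks for C2f-Faster, `S` and `C` substitute the pyramid-pooling and
attention blocks, and `IF`/`IFS`/`IFSC` stack the substitutions. The full
IFSC model ends up around 1.57 M parameters and 5.0 GFLOPs — the ~40 %/23 %
savings over the baseline that motivate the design. The other examples
(`examples/02…05`) walk through scene synthesis with occlusion, the dataset
pipeline (SSIM filter → 108/216/515 stratified split → 241 augmented
derivatives), a short training run, and single-image inference.

A thin CLI mirrors the library: `yolo-ifsc profile --variant all`,
`yolo-ifsc synth --images 120 --seed 42 --out data/`,
`yolo-ifsc train --variant IFSC --data data/ --epochs 30`.

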