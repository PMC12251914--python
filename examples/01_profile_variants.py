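"""Profile the complexity of every detector variant.

Builds each named configuration (baseline YOLOv11n, the single-module
variants I/F/S/C, and the combined IF/IFS/IFSC ladder), counts learnable
parameters exactly and tallies FLOPs for one 640x640 forward pass.  The
printed M/G columns are the numbers the lightweight design is judged by:
IFSC should come out around 1.6 M parameters and 5 GFLOPs, roughly 40 %
smaller and 23 % cheaper than the baseline.
"""

from yolo_ifsc.complexity import profile_variant

NAMES = ["baseline", "I-pos1", "I", "F-pos2", "S", "C", "IF", "IFS", "IFSC"]

print(f"{'variant':10s} {'params':>9s} {'M':>6s} {'FLOPs':>13s} {'G':>5s}")
for name in NAMES:
    r = profile_variant(name)
    print(f"{name:10s} {r.total_params:9d} {r.params_m:6.2f} "
          f"{r.total_flops:13d} {r.flops_g:5.1f}")

base = profile_variant("baseline")
ifsc = profile_variant("IFSC")
print(f"\nIFSC vs baseline: {100 * (1 - ifsc.total_params / base.total_params):.1f}% "
      f"fewer parameters, {100 * (1 - ifsc.total_flops / base.total_flops):.1f}% fewer FLOPs")
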