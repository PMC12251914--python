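"""Deterministic parameter and FLOP accounting for built detector variants.

Parameters are counted by exact enumeration of every learnable array in the
model (convolution kernels, biases, normalisation scale/shift pairs, fusion
logits).  FLOPs use the dominant-cost convention: each convolution costs
k_h * k_w * C_in/g * C_out multiply--accumulates per output position, one
MAC being ``MAC_TO_FLOP`` (= 2) floating-point operations; attention matmuls
cost 2 FLOPs per MAC as well, normalisation 2 and activations 1 FLOP per
element, pooling k*k comparison ops per output element.  Residual additions
and fusion weighting are not counted.  Partial convolutions therefore cost
exactly the partial ratio P of the equivalent full convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ag
from . import nn
from .network import Model, build_variant

__all__ = ["ComplexityReport", "count_params", "count_flops", "profile_variant",
           "MAC_TO_FLOP"]

# single global convention constant converting multiply-accumulates to FLOPs
MAC_TO_FLOP = 2


@dataclass
class LayerRow:
    index: int
    kind: str
    params: int
    flops: int


@dataclass
class ComplexityReport:
    variant: str
    input_hw: int
    rows: list
    total_params: int
    total_flops: int

    @property
    def params_m(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_g(self) -> float:
        return round(self.total_flops / 1e9, 1)

    def as_table(self) -> str:
        lines = [f"# convention: FLOPs = {MAC_TO_FLOP} x conv MACs; "
                 "norm/act/pooling uncounted",
                 "layer\tkind\tparams\tflops"]
        for r in self.rows:
            lines.append(f"{r.index}\t{r.kind}\t{r.params}\t{r.flops}")
        lines.append(f"total\t{self.variant}\t{self.total_params}\t{self.total_flops}")
        lines.append(f"summary\t{self.variant}\t{self.params_m} M\t{self.flops_g} G")
        return "\n".join(lines)


def count_params(model: Model) -> int:
    """Exact count of learnable scalars in a built model."""
    return model.num_params()


def _layer_macs(layer: nn.Module, feats_in, idx, model: Model):
    """FLOPs of one graph layer via a profiled forward on zeros."""
    with nn.profile_macs() as prof:
        out = layer(feats_in)
    return prof.macs, out


def count_flops(model: Model, input_hw: int = 640) -> int:
    """Total FLOPs of one forward pass at the given square input size."""
    return profile_model(model, input_hw).total_flops


def profile_model(model: Model, input_hw: int = 640,
                  variant_name: str | None = None) -> ComplexityReport:
    if input_hw % 32:
        raise ValueError("input size must be divisible by 32")
    model.eval()
    x = ag.Tensor(np.zeros((1, 3, input_hw, input_hw), dtype=np.float32))
    rows = []
    outs = []
    y = x
    with ag.no_grad():
        for i, (frm, layer) in enumerate(zip(model.routes, model.layers)):
            if isinstance(frm, int):
                inp = y if frm == -1 else outs[frm]
            else:
                inp = [y if f == -1 else outs[f] for f in frm]
            flops, y = _layer_macs(layer, inp, i, model)
            outs.append(y)
            rows.append(LayerRow(i, model.kinds[i], layer.num_params(), flops))
    total_p = sum(r.params for r in rows)
    total_f = sum(r.flops for r in rows)
    assert total_p == count_params(model)
    return ComplexityReport(variant_name or model.spec.name, input_hw, rows,
                            total_p, total_f)


def profile_variant(name: str, num_classes: int = 24,
                    input_hw: int = 640) -> ComplexityReport:
    """Build a registry variant and return its complexity report."""
    model = build_variant(name, num_classes=num_classes)
    return profile_model(model, input_hw, variant_name=name)
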