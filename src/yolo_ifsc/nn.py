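"""Network building blocks for the YOLO-IFSC detector family.

Implements both the YOLOv11n baseline blocks (CBS convolution unit, C3k2,
SPPF, C2PSA, anchor-free decoupled head) and the four bespoke lightweight
blocks: the multi-branch dynamically fused Inception-F, the partial
convolution C2f-Faster, the parallel pyramid SPPELANF, and CBAM dual
attention.

Every block is a :class:`Module` whose learnable arrays are discoverable via
``named_parameters`` (the complexity profiler enumerates exactly those) and
which records the multiply--accumulate cost of its convolutions during a
forward pass when profiling is switched on.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import autodiff as ag
from .autodiff import Parameter, Tensor

# ---------------------------------------------------------------------------
# module infrastructure
# ---------------------------------------------------------------------------


class Module:
    """Tiny nn.Module analogue: parameter registry, train/eval mode, MAC hook."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        for n, p in self.named_parameters():
            out[n] = p.data.copy()
        stack = [("", self)]
        while stack:
            prefix, m = stack.pop()
            for bn, b in m._buffers.items():
                out[prefix + bn] = np.asarray(b).copy()
            for mn, sub in m._modules.items():
                stack.append((prefix + mn + ".", sub))
        return out

    def load_state_dict(self, sd: dict):
        for n, p in self.named_parameters():
            p.data[...] = sd[n]
        stack = [("", self)]
        while stack:
            prefix, m = stack.pop()
            for bn in m._buffers:
                m._buffers[bn][...] = sd[prefix + bn]
            for mn, sub in m._modules.items():
                stack.append((prefix + mn + ".", sub))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


_PROFILE: Optional[dict] = None


class profile_macs:
    """Context manager accumulating convolution multiply--accumulate counts."""

    def __enter__(self):
        global _PROFILE
        self._prev = _PROFILE
        _PROFILE = {"macs": 0}
        return self

    def __exit__(self, *exc):
        global _PROFILE
        self.macs = _PROFILE["macs"]
        _PROFILE = self._prev
        return False


def _record_macs(n: int):
    """Convolution / matmul multiply-accumulates (2 FLOPs each)."""
    if _PROFILE is not None:
        _PROFILE["macs"] += 2 * n


def _record_ops(n: int):
    """Plain elementwise/comparison operations (1 FLOP each)."""
    if _PROFILE is not None:
        _PROFILE["macs"] += n


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Bare convolution (no norm/activation)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, d=1, g=1, bias=True, rng=None):
        super().__init__()
        if c1 <= 0 or c2 <= 0:
            raise ValueError("channel counts must be positive")
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.p = (d * (k - 1)) // 2 if p is None else p
        self.d, self.g = d, g
        if c1 % g or c2 % g:
            raise ValueError(f"groups={g} must divide both c1={c1} and c2={c2}")
        rng = rng or np.random.default_rng(0)
        fan_in = c1 // g * k * k
        self.weight = Parameter(_kaiming(rng, (c2, c1 // g, k, k), fan_in))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def macs(self, ho, wo) -> int:
        return (self.k * self.k * self.c1 // self.g) * self.c2 * ho * wo

    def forward(self, x: Tensor) -> Tensor:
        y = ag.conv2d(x, self.weight, self.bias, self.s, self.p, self.d, self.g)
        _record_macs(self.macs(y.shape[2], y.shape[3]))
        return y


class BatchNorm2d(Module):
    def __init__(self, c):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        _record_ops(2 * x.data.size)
        return ag.batch_norm(x, self.gamma, self.beta,
                             self._buffers["running_mean"],
                             self._buffers["running_var"], self.training)


class Conv(Module):
    """CBS unit: convolution + batch normalisation + activation.

    The convolution carries no bias (the normalisation shift absorbs it), so
    its learnable budget is k^2*C_in/g*C_out + 2*C_out, matching the standard
    parameter accounting for conv+BN stacks.
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, d=1, g=1, act="silu", rng=None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        if s < 1:
            raise ValueError("stride must be >= 1")
        self.conv = Conv2d(c1, c2, k, s, p, d, g, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        if self.act is not None and self.act != "identity":
            _record_ops(y.data.size)
        if self.act == "silu":
            return y.silu()
        if self.act == "leaky":
            return y.leaky_relu(0.1)
        if self.act is None or self.act == "identity":
            return y
        raise ValueError(f"unknown activation {self.act!r}")


class MaxPool(Module):
    def __init__(self, k, s=1, p=None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x):
        y = ag.max_pool2d(x, self.k, self.s, self.p)
        _record_ops(self.k * self.k * y.data.size)
        return y


class AvgPool(Module):
    def __init__(self, k, s=1, p=None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x):
        y = ag.avg_pool2d(x, self.k, self.s, self.p)
        _record_ops(self.k * self.k * y.data.size)
        return y


class Upsample(Module):
    def forward(self, x):
        return ag.upsample_nearest2x(x)


class Concat(Module):
    def forward(self, xs):
        return ag.concat(xs, axis=1)


# ---------------------------------------------------------------------------
# YOLOv11 baseline blocks
# ---------------------------------------------------------------------------


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, g=1, k=(3, 3), e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], 1, rng=rng)
        self.cv2 = Conv(c_, c2, k[1], 1, g=g, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    def __init__(self, c1, c2, n=1, shortcut=True, g=1, e=0.5, k=3, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, 1, rng=rng)
        self.m = Sequential(*[Bottleneck(c_, c_, shortcut, g, k=(k, k), e=1.0, rng=rng)
                              for _ in range(n)])

    def forward(self, x):
        return self.cv3(ag.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(Module):
    """Cross-stage block of YOLOv11 (C2f topology with optional C3k units)."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, g=1, shortcut=True, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, 1, rng=rng)
        self.m = ModuleList([
            C3k(self.c, self.c, 2, shortcut, g, rng=rng) if c3k
            else Bottleneck(self.c, self.c, shortcut, g, rng=rng)
            for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        c = self.c
        ys = [y[:, :c], y[:, c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


class SPPF(Module):
    """Serial same-kernel max-pool pyramid (baseline pooling block)."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv2 = Conv(4 * c_, c2, 1, 1, rng=rng)
        self.pool = MaxPool(k, 1, k // 2)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(ag.concat([y0, y1, y2, y3], axis=1))


class Attention(Module):
    """Multi-head self-attention over spatial positions (C2PSA interior)."""

    def __init__(self, dim, num_heads=8, attn_ratio=0.5, rng=None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = Conv(dim, h, 1, act=None, rng=rng)
        self.proj = Conv(dim, dim, 1, act=None, rng=rng)
        self.pe = Conv(dim, dim, 3, 1, g=dim, act=None, rng=rng)

    def forward(self, x):
        n, c, hh, ww = x.shape
        npos = hh * ww
        qkv = self.qkv(x)
        qkv = qkv.reshape(n, self.num_heads, self.key_dim * 2 + self.head_dim, npos)
        q = qkv[:, :, :self.key_dim]
        k = qkv[:, :, self.key_dim:2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        _record_macs(self.num_heads * npos * npos * (self.key_dim + self.head_dim))
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = v @ attn.transpose(0, 1, 3, 2)
        out = out.reshape(n, c, hh, ww)
        out = out + self.pe(v.reshape(n, c, hh, ww))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c, attn_ratio=0.5, num_heads=4, rng=None):
        super().__init__()
        self.attn = Attention(c, num_heads, attn_ratio, rng=rng)
        self.ffn = Sequential(Conv(c, c * 2, 1, rng=rng),
                              Conv(c * 2, c, 1, act=None, rng=rng))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(Module):
    """Cross-stage partial self-attention block (baseline p10)."""

    def __init__(self, c1, c2, n=1, e=0.5, rng=None):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = Conv(2 * self.c, c1, 1, rng=rng)
        self.m = Sequential(*[PSABlock(self.c, 0.5, max(1, self.c // 64), rng=rng)
                              for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        b = self.m(b)
        return self.cv2(ag.concat([a, b], axis=1))


# ---------------------------------------------------------------------------
# Inception-F: five-path block with softmax-weighted dynamic fusion
# ---------------------------------------------------------------------------


def _divisor_le(c: int, g: int) -> int:
    """Largest divisor of ``c`` that is <= g (clamps group counts)."""
    g = max(1, min(g, c))
    while c % g:
        g -= 1
    return g


class InceptionF(Module):
    """Multi-branch dynamic-fusion block.

    Five parallel paths at the input width --- dilated depthwise 3x3 (R1),
    dilated depthwise 5x5 (R2), grouped pointwise (R3), max pooling (R4) and
    average pooling (R5) --- each followed by a grouped pointwise projection
    to the output width, fused as a softmax-weighted sum of path outputs.
    Variant "A" keeps R1--R3, "B" adds R4, "F" uses all five paths; the
    softmax runs over the active path logits only.

    ``stride=2`` gives the downsampling form used at backbone placements
    (depthwise convs and pools run at stride 2); with the default stride 1
    spatial size is preserved.
    """

    PATHS = {"A": 3, "B": 4, "F": 5}

    def __init__(self, c1, c2, variant="F", stride=1, pw_groups=16,
                 r3_groups=16, rng=None):
        super().__init__()
        if variant not in self.PATHS:
            raise ValueError(f"unknown Inception-F variant {variant!r}")
        self.variant = variant
        self.n_paths = self.PATHS[variant]
        self.c1, self.c2, self.stride = c1, c2, stride
        gp = math.gcd(c1, c2)
        g_pw = _divisor_le(gp, pw_groups)
        g_r3 = _divisor_le(gp, r3_groups)
        # R1/R2: depthwise separable with dilation 2 (paddings preserve size
        # at stride 1), followed by grouped pointwise projection.
        self.r1_dw = Conv(c1, c1, 3, stride, p=2, d=2, g=c1, rng=rng)
        self.r1_pw = Conv(c1, c2, 1, g=g_pw, rng=rng)
        self.r2_dw = Conv(c1, c1, 5, stride, p=4, d=2, g=c1, rng=rng)
        self.r2_pw = Conv(c1, c2, 1, g=g_pw, rng=rng)
        # R3: grouped 1x1 channel fusion.
        self.r3 = Conv(c1, c2, 1, stride, p=0, g=g_r3, rng=rng)
        if self.n_paths >= 4:
            self.r4_pool = MaxPool(3, stride, 1)
            self.r4_pw = Conv(c1, c2, 1, g=g_pw, rng=rng)
        if self.n_paths >= 5:
            self.r5_pool = AvgPool(3, stride, 1)
            self.r5_pw = Conv(c1, c2, 1, g=g_pw, rng=rng)
        # one learnable fusion logit per active path, zero-initialised so the
        # block starts as an unbiased average of its paths
        self.fusion_logits = Parameter(np.zeros(self.n_paths, dtype=np.float32))

    def path_outputs(self, x: Tensor) -> list[Tensor]:
        outs = [self.r1_pw(self.r1_dw(x)), self.r2_pw(self.r2_dw(x)), self.r3(x)]
        if self.n_paths >= 4:
            outs.append(self.r4_pw(self.r4_pool(x)))
        if self.n_paths >= 5:
            outs.append(self.r5_pw(self.r5_pool(x)))
        return outs

    def forward(self, x):
        return dynamic_weight_fusion(self.fusion_logits, self.path_outputs(x))


def dynamic_weight_fusion(logits: Tensor, paths: list[Tensor]) -> Tensor:
    """softmax-normalised weighted sum of equally shaped feature maps."""
    shape = paths[0].shape
    for p in paths[1:]:
        if p.shape != shape:
            raise ValueError(f"fusion path shape mismatch: {p.shape} vs {shape}")
    w = logits.softmax(axis=0)
    out = w[0] * paths[0]
    for i in range(1, len(paths)):
        out = out + w[i] * paths[i]
    return out


# ---------------------------------------------------------------------------
# C2f-Faster: partial-convolution bottleneck in a C2f shell
# ---------------------------------------------------------------------------


class PConv(Module):
    """Partial convolution: a k x k conv over the first ceil(P*C) channels,
    identity on the rest.

    Its accounted cost is the fraction P of the equivalent full convolution
    (k*k*C*C*H*W*P multiply--accumulates), the standard complexity claim for
    partial convolution.
    """

    def __init__(self, c, k=3, partial_ratio=0.25, rng=None):
        super().__init__()
        if not 0.0 < partial_ratio <= 1.0:
            raise ValueError("partial ratio must lie in (0, 1]")
        self.c = c
        self.k = k
        self.cp = max(1, math.ceil(partial_ratio * c))
        self.partial_ratio = partial_ratio
        self.conv = Conv2d(self.cp, self.cp, k, 1, bias=False, rng=rng)

    def macs(self, ho, wo) -> int:
        return int(round(self.k * self.k * self.c * self.c * ho * wo
                         * self.partial_ratio))

    def forward(self, x):
        if self.cp == self.c:
            y = self.conv(x)
        else:
            head = self.conv(x[:, :self.cp])
            y = ag.concat([head, x[:, self.cp:]], axis=1)
        # replace the raw conv count with the partial-ratio convention
        _record_macs(self.macs(y.shape[2], y.shape[3])
                     - self.conv.macs(y.shape[2], y.shape[3]))
        return y


class FasterBottleneck(Module):
    """PConv followed by two pointwise convs with a residual connection."""

    def __init__(self, c, expansion=0.5, partial_ratio=0.25, rng=None):
        super().__init__()
        c_h = int(c * expansion)
        self.pconv = PConv(c, 3, partial_ratio, rng=rng)
        self.cv1 = Conv(c, c_h, 1, rng=rng)
        self.cv2 = Conv(c_h, c, 1, act=None, rng=rng)

    def forward(self, x):
        return x + self.cv2(self.cv1(self.pconv(x)))


class C2fFaster(Module):
    def __init__(self, c1, c2, n=1, e=0.5, expansion=0.5, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError("need at least one bottleneck")
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, rng=rng)
        self.m = ModuleList([FasterBottleneck(self.c, expansion, rng=rng)
                             for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        c = self.c
        ys = [y[:, :c], y[:, c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


# ---------------------------------------------------------------------------
# SPPELANF: parallel pyramid pooling with cross-layer 1x1 fusion
# ---------------------------------------------------------------------------


class SPPELANF(Module):
    """Chained 5x5 max pools with per-stage 1x1 alignment convs, channel
    concatenation and a final pointwise projection to the output width.

    The 1x1 CBS units inside use LeakyReLU activation; ``c_star`` is the
    intermediate pyramid width.
    """

    def __init__(self, c1, c2, c_star=None, fpn=True, rng=None):
        super().__init__()
        if c1 < 2:
            raise ValueError("input width must be >= 2")
        self.c_star = c_star if c_star is not None else max(1, c1 // 16)
        self.fpn = fpn
        self.cv1 = Conv(c1, self.c_star, 1, act="leaky", rng=rng)
        self.pool = MaxPool(5, 1, 2)
        if fpn:
            self.f = ModuleList([Conv(self.c_star, self.c_star, 1, act="leaky", rng=rng)
                                 for _ in range(3)])
        self.proj = Conv(4 * self.c_star, c2, 1, act="leaky", rng=rng)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        if self.fpn:
            feats = [y0, self.f[0](y1), self.f[1](y2), self.f[2](y3)]
        else:
            feats = [y0, y1, y2, y3]
        z = ag.concat(feats, axis=1)
        return self.proj(z)


class SPPELAN(SPPELANF):
    """Parallel pyramid without the cross-layer 1x1 fusion convs."""

    def __init__(self, c1, c2, c_star=None, rng=None):
        super().__init__(c1, c2, c_star, fpn=False, rng=rng)


# ---------------------------------------------------------------------------
# CBAM: channel then spatial attention
# ---------------------------------------------------------------------------


class ChannelAttention(Module):
    def __init__(self, c, reduction=16, rng=None):
        super().__init__()
        hidden = max(1, c // reduction)
        self.fc1 = Conv2d(c, hidden, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, c, 1, bias=True, rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        a = self.fc2(self.fc1(avg).leaky_relu(0.0))  # ReLU between MLP layers
        m = self.fc2(self.fc1(mx).leaky_relu(0.0))
        return (a + m).sigmoid()

    def forward(self, x):
        return self.attention(x) * x


class SpatialAttention(Module):
    def __init__(self, k=7, rng=None):
        super().__init__()
        self.conv = Conv2d(2, 1, k, 1, p=k // 2, bias=True, rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(ag.concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x):
        return self.attention(x) * x


class CBAM(Module):
    """Sequential channel + spatial attention gates, each sigmoid-squashed."""

    def __init__(self, c, reduction=16, rng=None):
        super().__init__()
        self.channel = ChannelAttention(c, reduction, rng=rng)
        self.spatial = SpatialAttention(7, rng=rng)

    def forward(self, x):
        return self.spatial(self.channel(x))


# ---------------------------------------------------------------------------
# detection head
# ---------------------------------------------------------------------------


class DWConv(Conv):
    def __init__(self, c1, c2, k=3, s=1, act="silu", rng=None):
        super().__init__(c1, c2, k, s, g=math.gcd(c1, c2), act=act, rng=rng)


class Detect(Module):
    """Anchor-free decoupled head over three scales (strides 8/16/32).

    Each scale emits 4*reg_max box-distribution logits and ``nc`` class
    logits; the box branch uses two 3x3 convs, the class branch the
    lightweight depthwise-separable stem.
    """

    def __init__(self, nc, ch=(64, 128, 256), reg_max=16, rng=None):
        super().__init__()
        if nc < 1:
            raise ValueError("need at least one class")
        self.nc, self.reg_max = nc, reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box = ModuleList([
            Sequential(Conv(c, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                       Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            for c in ch])
        self.cls = ModuleList([
            Sequential(DWConv(c, c, 3, rng=rng), Conv(c, c3, 1, rng=rng),
                       DWConv(c3, c3, 3, rng=rng), Conv(c3, c3, 1, rng=rng),
                       Conv2d(c3, nc, 1, bias=True, rng=rng))
            for c in ch])
        # bias priors: mild negative class prior stabilises early training
        for seq in self.cls:
            seq._list[-1].bias.data[...] = -4.0

    def forward(self, feats: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        """Returns per-scale (box_logits, cls_logits) pairs (N,*,H,W)."""
        return [(self.box[i](f), self.cls[i](f)) for i, f in enumerate(feats)]
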