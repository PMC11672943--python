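"""A MobileViTv2-style image backbone (separable self-attention).

Light hybrid CNN/transformer classifier used for the facial-landmark
pseudo-color images.  The stage plan follows the published recipe: a
strided 3x3 stem, inverted-residual (MV2) stages, then three stages that
append a transformer block operating on 2x2 patch unfoldings with
*separable* self-attention — a single context score per token replaces
the full attention matrix, keeping cost linear in token count.  All
channel widths scale with a single width multiplier; at multiplier 1.5
the canonical 1000-class model counts ~10.6 M parameters.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor

__all__ = ["MobileViTv2", "make_divisible"]


def make_divisible(v: float, divisor: int = 8, min_value: int | None = None) -> int:
    """Round a scaled channel count to a hardware-friendly multiple."""
    if min_value is None:
        min_value = divisor
    new_v = max(min_value, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return int(new_v)


def _conv_bn_act(cin, cout, kernel, stride=1, groups=1, act=True, rng=None):
    pad = (kernel - 1) // 2
    layers = [nn.Conv2d(cin, cout, kernel, stride=stride, padding=pad,
                        groups=groups, bias=False, rng=rng),
              nn.BatchNorm2d(cout)]
    if act:
        layers.append(nn.SiLU())
    return nn.Sequential(*layers)


class MV2Block(nn.Module):
    """MobileNetV2 inverted residual: expand 1x1 -> depthwise 3x3 -> project."""

    def __init__(self, cin, cout, stride=1, expand=2, rng=None):
        super().__init__()
        hidden = cin * expand
        self.expand = _conv_bn_act(cin, hidden, 1, rng=rng)
        self.depthwise = _conv_bn_act(hidden, hidden, 3, stride=stride,
                                      groups=hidden, rng=rng)
        self.project = _conv_bn_act(hidden, cout, 1, act=False, rng=rng)
        self.use_residual = stride == 1 and cin == cout

    def forward(self, x):
        y = self.project(self.depthwise(self.expand(x)))
        return x + y if self.use_residual else y


class SeparableSelfAttention(nn.Module):
    """Linear-complexity attention: softmax context scores over tokens."""

    def __init__(self, dim: int, rng=None):
        super().__init__()
        self.dim = dim
        self.qkv = nn.Conv2d(dim, 1 + 2 * dim, 1, rng=rng)
        self.out_proj = nn.Conv2d(dim, dim, 1, rng=rng)

    def forward(self, x):
        # x: (N, d, P, Np) — P pixels per patch, Np patches (tokens)
        d = self.dim
        qkv = self.qkv(x)
        scores = qkv[:, 0:1]                       # (N, 1, P, Np)
        key = qkv[:, 1:1 + d]
        value = qkv[:, 1 + d:]
        context_scores = scores.softmax(axis=-1)
        context = (key * context_scores).sum(axis=-1, keepdims=True)  # (N, d, P, 1)
        return self.out_proj(value.relu() * context)


class LinearAttnFFN(nn.Module):
    def __init__(self, dim: int, ffn_dim: int, rng=None):
        super().__init__()
        self.norm1 = nn.GroupNorm(1, dim)
        self.attn = SeparableSelfAttention(dim, rng=rng)
        self.norm2 = nn.GroupNorm(1, dim)
        self.ffn = nn.Sequential(nn.Conv2d(dim, ffn_dim, 1, rng=rng), nn.SiLU(),
                                 nn.Conv2d(ffn_dim, dim, 1, rng=rng))

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class MobileViTBlockV2(nn.Module):
    """Local depthwise rep -> patch unfold -> transformer -> fold -> project."""

    def __init__(self, cin: int, attn_dim: int, n_blocks: int,
                 patch: tuple = (2, 2), ffn_mult: float = 2.0, rng=None):
        super().__init__()
        self.local_dw = _conv_bn_act(cin, cin, 3, groups=cin, rng=rng)
        self.local_proj = nn.Conv2d(cin, attn_dim, 1, bias=False, rng=rng)
        ffn_dim = int((ffn_mult * attn_dim) // 16 * 16)
        self.transformer = [LinearAttnFFN(attn_dim, ffn_dim, rng=rng)
                            for _ in range(n_blocks)]
        self.norm = nn.GroupNorm(1, attn_dim)
        self.out_proj = _conv_bn_act(attn_dim, cin, 1, act=False, rng=rng)
        self.patch = patch

    def forward(self, x):
        y = self.local_proj(self.local_dw(x))
        N, d, H, W = y.shape
        ph, pw = self.patch
        if H % ph or W % pw:
            raise ValueError(f"feature map ({H},{W}) not divisible by patch {self.patch}")
        # unfold: (N, d, H, W) -> (N, d, ph*pw, (H/ph)*(W/pw))
        y = (y.reshape(N, d, H // ph, ph, W // pw, pw)
             .transpose(0, 1, 3, 5, 2, 4)
             .reshape(N, d, ph * pw, (H // ph) * (W // pw)))
        for block in self.transformer:
            y = block(y)
        y = self.norm(y)
        y = (y.reshape(N, d, ph, pw, H // ph, W // pw)
             .transpose(0, 1, 4, 2, 5, 3)
             .reshape(N, d, H, W))
        return self.out_proj(y)


class MobileViTv2(nn.Module):
    """The classifier: width-scaled stages, global pool, linear head.

    ``width`` scales every stage; ``num_classes`` sizes the head (1000 in
    the canonical configuration, 6 for the behaviour task, 3 for the
    arousal protocol).
    """

    def __init__(self, width: float = 1.5, num_classes: int = 1000,
                 in_channels: int = 3, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        w = width
        c0 = make_divisible(min(64, max(16, 32 * w)), 8, 16)
        c1 = make_divisible(64 * w, 16)
        c2 = make_divisible(128 * w, 8)
        c3, d3 = make_divisible(256 * w, 8), make_divisible(128 * w, 8)
        c4, d4 = make_divisible(384 * w, 8), make_divisible(192 * w, 8)
        c5, d5 = make_divisible(512 * w, 8), make_divisible(256 * w, 8)
        self.stem = _conv_bn_act(in_channels, c0, 3, stride=2, rng=rng)
        self.layer1 = MV2Block(c0, c1, 1, rng=rng)
        self.layer2 = nn.Sequential(MV2Block(c1, c2, 2, rng=rng),
                                    MV2Block(c2, c2, 1, rng=rng))
        self.layer3 = nn.Sequential(MV2Block(c2, c3, 2, rng=rng),
                                    MobileViTBlockV2(c3, d3, 2, rng=rng))
        self.layer4 = nn.Sequential(MV2Block(c3, c4, 2, rng=rng),
                                    MobileViTBlockV2(c4, d4, 4, rng=rng))
        self.layer5 = nn.Sequential(MV2Block(c4, c5, 2, rng=rng),
                                    MobileViTBlockV2(c5, d5, 3, rng=rng))
        self.fc = nn.Linear(c5, num_classes, rng=rng)
        self.feature_dim = c5

    def features(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        x = self.layer1(x)
        x = self.layer2(x)
        x = self.layer3(x)
        x = self.layer4(x)
        x = self.layer5(x)
        return nn.global_avg_pool(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))
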