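"""Attention-Enhanced Decoder (AED).

Four Up-Concat stages rebuild resolution from the fused deep features: each
stage upsamples 2x, concatenates the matching skip (fused feat4 first, then
the RGB branch's feat3/feat2/feat1), recalibrates the concatenation with a
channel+spatial attention block (CBAM), and refines with a double
conv-norm-activation block.  A final 2x upsample and 1x1 classifier head
emit two-class logits at the input resolution.

CBAM runs channel-then-spatial sequentially by default (the spatial map is
computed on the channel-refined features); a ``parallel`` variant computing
both maps on the raw input and multiplying them jointly is available, as is
an ablation switch that removes CBAM entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concat, relu, sigmoid, upsample_bilinear_2x

__all__ = [
    "DecoderConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "UpConcat",
    "Decoder",
]


@dataclass(frozen=True)
class DecoderConfig:
    cbam_reduction: int = 16
    cbam_enabled: bool = True
    cbam_order: str = "sequential"        # or "parallel"
    upsample_mode: str = "bilinear"       # or "transposed"
    spatial_kernel: int = 7
    n_classes: int = 2

    def validate(self) -> None:
        if self.cbam_order not in ("sequential", "parallel"):
            raise ValueError("cbam_order must be 'sequential' or 'parallel'")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError("upsample_mode must be 'bilinear' or 'transposed'")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial attention kernel must be odd")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class ChannelAttention(nn.Module):
    """Sigmoid channel weights from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction: int, *, rng: np.random.Generator):
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction "
                f"({reduction})")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(v)))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        flat = x.reshape(b, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        return sigmoid(self._mlp(avg) + self._mlp(mx))   # (B, C) in (0,1)


class SpatialAttention(nn.Module):
    """Sigmoid spatial weights from channel-pooled planes through a kxk conv."""

    def __init__(self, kernel: int = 7, *, rng: np.random.Generator):
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))  # (B,1,H,W)


class CBAM(nn.Module):
    """Channel + spatial recalibration; both attention factors lie in (0,1),
    so the output is an elementwise contraction of the input."""

    def __init__(self, channels: int, reduction: int = 16,
                 order: str = "sequential", spatial_kernel: int = 7,
                 *, rng: np.random.Generator):
        self.order = order
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        mc = self.channel(x).reshape(b, c, 1, 1)
        if self.order == "parallel":
            return x * mc * self.spatial(x)
        refined = x * mc
        return refined * self.spatial(refined)


class _TransposedUp(nn.Module):
    """2x learnable upsampling: each pixel expands to a 2x2 block."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator):
        self.out_ch = out_ch
        self.weight = nn.Parameter(nn.trunc_normal((in_ch, out_ch * 4), 0.02, rng))
        self.bias = nn.Parameter(np.zeros(out_ch * 4, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w).transpose(0, 2, 1)           # (B, HW, C)
        y = flat @ self.weight + self.bias                         # (B, HW, 4*out)
        y = y.reshape(b, h, w, self.out_ch, 2, 2)
        y = y.transpose(0, 3, 1, 4, 2, 5)                          # (B,out,H,2,W,2)
        return y.reshape(b, self.out_ch, 2 * h, 2 * w)


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator):
        self.block = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng),
            nn.LayerNormChannels(out_ch),
            nn.GELU(),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng),
            nn.LayerNormChannels(out_ch),
            nn.GELU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class UpConcat(nn.Module):
    """2x upsample the deep map, concatenate the skip, CBAM, double conv."""

    def __init__(self, deep_ch: int, skip_ch: int, out_ch: int,
                 config: DecoderConfig, *, rng: np.random.Generator):
        config.validate()
        if config.upsample_mode == "transposed":
            self.up = _TransposedUp(deep_ch, skip_ch, rng=rng)
        else:
            self.up = nn.Sequential(_Bilinear2x(),
                                    nn.Conv2d(deep_ch, skip_ch, 3, padding=1,
                                              rng=rng))
        cat_ch = 2 * skip_ch
        self.cbam = (CBAM(cat_ch, config.cbam_reduction, config.cbam_order,
                          config.spatial_kernel, rng=rng)
                     if config.cbam_enabled else nn.Identity())
        self.conv = _DoubleConv(cat_ch, out_ch, rng=rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self.up(deep)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"skip spatial size {skip.shape[2:]} does not match "
                f"upsampled deep size {up.shape[2:]}")
        # concatenation order is (upsampled deep, skip)
        return self.conv(self.cbam(concat([up, skip], axis=1)))


class _Bilinear2x(nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_bilinear_2x(x)


class Decoder(nn.Module):
    """Four Up-Concat stages plus a 2x upsample + 1x1 classifier head.

    ``widths`` is the encoder ladder (c1..c5); stage i consumes a deep map of
    width c_{5-i+1} and a skip of width c_{5-i}.
    """

    def __init__(self, widths: tuple, config: DecoderConfig,
                 *, rng: np.random.Generator):
        config.validate()
        self.config = config
        c1, c2, c3, c4, c5 = widths
        self.stage1 = UpConcat(c5, c4, c4, config, rng=rng)
        self.stage2 = UpConcat(c4, c3, c3, config, rng=rng)
        self.stage3 = UpConcat(c3, c2, c2, config, rng=rng)
        self.stage4 = UpConcat(c2, c1, c1, config, rng=rng)
        self.head = nn.Conv2d(c1, config.n_classes, 1, rng=rng)

    def forward(self, fused5: Tensor, fused4: Tensor, feat3: Tensor,
                feat2: Tensor, feat1: Tensor) -> Tensor:
        y = self.stage1(fused5, fused4)
        y = self.stage2(y, feat3)
        y = self.stage3(y, feat2)
        y = self.stage4(y, feat1)
        return self.head(upsample_bilinear_2x(y))
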