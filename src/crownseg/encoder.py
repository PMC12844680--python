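"""Dual-branch hierarchical encoder.

Two independent ConvNeXt-style backbones extract features per modality: the
RGB branch exposes five levels (feat1 at 1/2 resolution through feat5 at
1/32), the multispectral branch runs the same architecture on four bands but
exposes only the two deepest levels (feat4, feat5), concentrating on
high-level spectral semantics and keeping shallow spectral noise out of the
decoder's skip connections.

The backbone stem patchifies at stride 4, so feat1 (needed by the decoder's
shallowest skip) comes from an auxiliary conv-norm-activation block at
stride 2.  A channel-extension initializer lets a 4-band stem inherit a
3-band pretrained filter bank, drawing the extra band's filters from a
zero-mean Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .synthetic import MS_BANDS

__all__ = [
    "EncoderConfig",
    "FeaturePyramid",
    "ConvNeXtBackbone",
    "BranchEncoder",
    "extend_first_conv",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Backbone hyperparameters; defaults are the Tiny ladder."""

    in_channels: int = 3
    depths: tuple = (3, 3, 9, 3)
    dims: tuple = (96, 192, 384, 768)     # stage widths (feat2..feat5)
    stem_width: int = 48                  # feat1 width (auxiliary 1/2-res block)
    width_multiplier: float = 1.0
    pretrained: bool = False              # random init when False (offline builds)
    layer_scale_init: float = 1e-6
    extend_sigma: float = 0.01            # std for extra-band stem filters
    band_order: tuple = MS_BANDS

    def validate(self) -> None:
        if self.in_channels not in (3, 4):
            raise ValueError("in_channels must be 3 (RGB) or 4 (MS)")
        widths = self.widths
        if any(w <= 0 for w in widths):
            raise ValueError("channel widths must be positive")
        if any(a > b for a, b in zip(widths, widths[1:])):
            raise ValueError("channel width ladder must be non-decreasing")
        if len(self.depths) != 4 or len(self.dims) != 4:
            raise ValueError("expected 4 stage depths and 4 stage widths")

    def _scale(self, w: int) -> int:
        return max(4, int(round(w * self.width_multiplier / 4.0)) * 4)

    @property
    def widths(self) -> tuple:
        """Scaled width ladder (c1..c5) after the width multiplier."""
        return (self._scale(self.stem_width),) + tuple(self._scale(d) for d in self.dims)

    @classmethod
    def test_scale(cls, in_channels: int = 3) -> "EncoderConfig":
        """Reduced desk-scale variant: quarter width, single-block stages."""
        return cls(in_channels=in_channels, depths=(1, 1, 1, 1),
                   width_multiplier=0.25)


LEVEL_STRIDES = {"feat1": 2, "feat2": 4, "feat3": 8, "feat4": 16, "feat5": 32}


@dataclass
class FeaturePyramid:
    """Ordered hierarchical feature maps keyed feat1..feat5 with a branch tag."""

    levels: dict
    branch: str = "rgb"

    def __getitem__(self, name: str) -> Tensor:
        if name not in self.levels:
            raise KeyError(
                f"level '{name}' absent from {self.branch} pyramid "
                f"(has {sorted(self.levels)})")
        return self.levels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.levels


class ConvNeXtBlock(nn.Module):
    """Depthwise 7x7 -> channel LayerNorm -> pointwise MLP (4x) -> layer scale,
    wrapped in a residual connection."""

    def __init__(self, dim: int, layer_scale_init: float, rng: np.random.Generator):
        self.dwconv = nn.DepthwiseConv2d(dim, 7, padding=3, rng=rng)
        self.norm = nn.LayerNormChannels(dim)
        self.pw1 = nn.Conv2d(dim, 4 * dim, 1, rng=rng)
        self.act = nn.GELU()
        self.pw2 = nn.Conv2d(4 * dim, dim, 1, rng=rng)
        self.layer_scale = nn.Parameter(
            np.full(dim, layer_scale_init, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.pw2(self.act(self.pw1(y)))
        scale = self.layer_scale.reshape(1, -1, 1, 1)
        return x + scale * y


class ConvNeXtBackbone(nn.Module):
    """Four-stage hierarchical backbone; stage outputs are feat2..feat5."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        dims = config.widths[1:]
        self.stem_conv = nn.Conv2d(config.in_channels, dims[0], 4, stride=4, rng=rng)
        self.stem_norm = nn.LayerNormChannels(dims[0])
        self.down_norms = nn.ModuleList(
            [nn.LayerNormChannels(dims[i]) for i in range(3)])
        self.down_convs = nn.ModuleList(
            [nn.Conv2d(dims[i], dims[i + 1], 2, stride=2, rng=rng)
             for i in range(3)])
        self.stages = nn.ModuleList()
        for i, depth in enumerate(config.depths):
            self.stages.append(nn.Sequential(*[
                ConvNeXtBlock(dims[i], config.layer_scale_init, rng)
                for _ in range(depth)]))

    def forward(self, x: Tensor) -> dict:
        feats = {}
        y = self.stem_norm(self.stem_conv(x))
        for i in range(4):
            if i > 0:
                y = self.down_convs[i - 1](self.down_norms[i - 1](y))
            y = self.stages[i](y)
            feats[f"feat{i + 2}"] = y
        return feats


class BranchEncoder(nn.Module):
    """One modality branch: auxiliary 1/2-resolution block + backbone.

    ``expose`` selects which pyramid levels the branch publishes — the RGB
    branch exposes all five, the MS branch only feat4/feat5.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 branch: str = "rgb",
                 expose=("feat1", "feat2", "feat3", "feat4", "feat5")):
        config.validate()
        self.config = config
        self.branch = branch
        self.expose = tuple(expose)
        if "feat1" in self.expose:   # the deep-only MS branch has no shallow path
            c1 = config.widths[0]
            self.aux_conv = nn.Conv2d(config.in_channels, c1, 3, stride=2,
                                      padding=1, rng=rng)
            self.aux_norm = nn.LayerNormChannels(c1)
            self.aux_act = nn.GELU()
        self.backbone = ConvNeXtBackbone(config, rng)

    def forward(self, x: Tensor) -> FeaturePyramid:
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"{self.branch} branch expects "
                             f"{self.config.in_channels} channels, got {c}")
        if h % 32 or w % 32:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by 32 "
                "(five stride-2 reductions)")
        levels = {}
        if "feat1" in self.expose:
            levels["feat1"] = self.aux_act(self.aux_norm(self.aux_conv(x)))
        feats = self.backbone(x)
        for name in self.expose:
            if name != "feat1":
                levels[name] = feats[name]
        return FeaturePyramid(levels=levels, branch=self.branch)


def extend_first_conv(weights3: np.ndarray, n_extra: int, sigma: float,
                      seed: int = 0) -> np.ndarray:
    """Extend a 3-input-channel stem filter bank to 3 + n_extra channels.

    The first three input-channel slices are copied verbatim; the extra
    slices are i.i.d. zero-mean Gaussian with standard deviation ``sigma``
    (how a pretrained visible-light stem is carried over to an extra
    narrow-band channel such as RedEdge).
    """
    weights3 = np.asarray(weights3, dtype=np.float32)
    if weights3.ndim != 4 or weights3.shape[1] != 3:
        raise ValueError("weights3 must have shape (out, 3, kh, kw)")
    if n_extra < 0:
        raise ValueError("n_extra must be non-negative")
    if n_extra == 0:
        return weights3.copy()
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    cout, _, kh, kw = weights3.shape
    extra = rng.normal(0.0, sigma, size=(cout, n_extra, kh, kw)).astype(np.float32)
    return np.concatenate([weights3.copy(), extra], axis=1)
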