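"""Cross-Modal Interactive Fusion (CIF).

At the two deepest pyramid levels each modality attends over the other:
1x1 convolutions produce queries/keys (at reduced width C/qk_reduction) and
full-width values, attention runs over the N = H*W spatial positions, and
the attended complement is added back through a learnable scalar gain
(gamma, initialized to 0 so the block starts as an exact identity).  The two
enhanced maps are then combined elementwise as ``alpha * F_rgb + beta *
F_ms`` with learnable scalars per stage, so fusion adapts the modality
balance without expanding channels.

No temperature or sqrt(d) scaling is applied inside the softmax, and the
attention is single-head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, softmax
from .encoder import FeaturePyramid

__all__ = ["CotSR", "WeightFusion", "CIF", "FusionConfig"]


@dataclass(frozen=True)
class FusionConfig:
    qk_reduction: int = 8
    gamma_init: float = 0.0
    alpha_init: float = 1.0
    beta_init: float = 1.0
    stages: tuple = ("feat4", "feat5")


class CotSR(nn.Module):
    """Bidirectional cross-attention between two same-shaped feature maps."""

    def __init__(self, channels: int, qk_reduction: int = 8,
                 gamma_init: float = 0.0, *, rng: np.random.Generator):
        cq = max(1, channels // qk_reduction)
        self.channels = channels
        self.q1 = nn.Conv2d(channels, cq, 1, rng=rng)
        self.k1 = nn.Conv2d(channels, cq, 1, rng=rng)
        self.v1 = nn.Conv2d(channels, channels, 1, rng=rng)
        self.q2 = nn.Conv2d(channels, cq, 1, rng=rng)
        self.k2 = nn.Conv2d(channels, cq, 1, rng=rng)
        self.v2 = nn.Conv2d(channels, channels, 1, rng=rng)
        self.gamma1 = nn.Parameter(np.float32(gamma_init))
        self.gamma2 = nn.Parameter(np.float32(gamma_init))
        self.last_attention: tuple | None = None  # numpy copies, for inspection

    def set_identity_projections(self):
        """Make every Q/K/V projection the identity (requires qk width == C)."""
        for proj in (self.q1, self.k1, self.v1, self.q2, self.k2, self.v2):
            cout, cin = proj.weight.data.shape[:2]
            if cout != cin:
                raise ValueError("identity projections need square 1x1 filters")
            proj.weight.data = np.eye(cout, dtype=np.float32).reshape(
                cout, cin, 1, 1)
            if proj.bias is not None:
                proj.bias.data = np.zeros(cout, dtype=np.float32)

    def _attend(self, q: Tensor, k: Tensor, v: Tensor, n_pos: int):
        b = q.shape[0]
        qf = q.reshape(b, q.shape[1], n_pos).transpose(0, 2, 1)   # (B, N, Cq)
        kf = k.reshape(b, k.shape[1], n_pos)                      # (B, Cq, N)
        attn = softmax(qf @ kf, axis=-1)                          # rows over keys
        vf = v.reshape(b, v.shape[1], n_pos)                      # (B, C, N)
        out = vf @ attn.transpose(0, 2, 1)                        # (B, C, N)
        return out, attn

    def forward(self, x1: Tensor, x2: Tensor):
        if x1.shape != x2.shape:
            raise ValueError(f"branch shapes disagree: {x1.shape} vs {x2.shape}")
        b, c, h, w = x1.shape
        n_pos = h * w
        out1, attn1 = self._attend(self.q1(x1), self.k2(x2), self.v2(x2), n_pos)
        out2, attn2 = self._attend(self.q2(x2), self.k1(x1), self.v1(x1), n_pos)
        y1 = x1 + self.gamma1 * out1.reshape(b, c, h, w)
        y2 = x2 + self.gamma2 * out2.reshape(b, c, h, w)
        self.last_attention = (attn1.data.copy(), attn2.data.copy())
        return y1, y2


class WeightFusion(nn.Module):
    """Elementwise ``alpha * F_rgb + beta * F_ms`` with learnable scalars."""

    def __init__(self, alpha_init: float = 1.0, beta_init: float = 1.0):
        self.alpha = nn.Parameter(np.float32(alpha_init))
        self.beta = nn.Parameter(np.float32(beta_init))

    def forward(self, f_rgb: Tensor, f_ms: Tensor) -> Tensor:
        if f_rgb.shape != f_ms.shape:
            raise ValueError(
                f"fusion shapes disagree: {f_rgb.shape} vs {f_ms.shape}")
        return self.alpha * f_rgb + self.beta * f_ms


class CIF(nn.Module):
    """Per-stage CotSR + dynamic weight fusion at feat4 and feat5."""

    def __init__(self, channels_by_stage: dict, config: FusionConfig,
                 *, rng: np.random.Generator):
        self.config = config
        self.cotsr = {}
        self.fusers = {}
        for stage in config.stages:
            cot = CotSR(channels_by_stage[stage], config.qk_reduction,
                        config.gamma_init, rng=rng)
            fuse = WeightFusion(config.alpha_init, config.beta_init)
            setattr(self, f"cotsr_{stage}", cot)
            setattr(self, f"fuse_{stage}", fuse)
            self.cotsr[stage] = cot
            self.fusers[stage] = fuse

    def named_parameters(self, prefix: str = ""):
        for stage in self.config.stages:
            for attr in (f"cotsr_{stage}", f"fuse_{stage}"):
                sub = f"{prefix}.{attr}" if prefix else attr
                yield from getattr(self, attr).named_parameters(sub)

    def fusion_weights(self) -> dict:
        """Current (alpha, beta) per stage — mirrors the training report."""
        return {stage: (float(f.alpha.data), float(f.beta.data))
                for stage, f in self.fusers.items()}

    def forward(self, rgb_pyr: FeaturePyramid, ms_pyr: FeaturePyramid) -> dict:
        fused = {}
        for stage in self.config.stages:
            x_rgb, x_ms = rgb_pyr[stage], ms_pyr[stage]
            y_rgb, y_ms = self.cotsr[stage](x_rgb, x_ms)
            fused[stage] = self.fusers[stage](y_rgb, y_ms)
        return fused
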