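"""Full dual-branch cross-modal segmentation model.

Workflow: the two branch encoders run in parallel (five RGB levels, two deep
MS levels), the cross-modal fusion block interacts and blends feat4/feat5,
and the attention-enhanced decoder rebuilds two-class logits at input
resolution using the RGB branch's shallow levels as skips.  Single-modality
variants reuse the identical decoder over one branch's own pyramid (the
fusion block is bypassed), enabling the RGB-only / MS-only / fused ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .decoder import Decoder, DecoderConfig
from .encoder import BranchEncoder, EncoderConfig
from .fusion import CIF, FusionConfig

__all__ = [
    "ModelConfig",
    "SegmentationOutput",
    "CrownFusionNet",
    "SingleModalityNet",
    "build_model",
    "build_single_modality_variant",
]


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0

    @classmethod
    def test_scale(cls, seed: int = 0) -> "ModelConfig":
        """Quarter-width, single-block-stage variant for desk-scale runs."""
        return cls(encoder=EncoderConfig.test_scale(),
                   decoder=DecoderConfig(cbam_reduction=4),
                   seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, blob: dict) -> "ModelConfig":
        enc = dict(blob.get("encoder", {}))
        for key in ("depths", "dims", "band_order"):
            if key in enc:
                enc[key] = tuple(enc[key])
        fus = dict(blob.get("fusion", {}))
        if "stages" in fus:
            fus["stages"] = tuple(fus["stages"])
        return cls(encoder=EncoderConfig(**enc),
                   fusion=FusionConfig(**fus),
                   decoder=DecoderConfig(**blob.get("decoder", {})),
                   seed=int(blob.get("seed", 0)))


@dataclass
class SegmentationOutput:
    logits: np.ndarray        # (H, W, n_classes)
    mask: np.ndarray          # (H, W) in {0, 1}; argmax, ties -> background
    probabilities: np.ndarray # (H, W, n_classes)


def _softmax_np(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _PredictMixin:
    def predict(self, rgb: np.ndarray, ms: np.ndarray) -> SegmentationOutput:
        """Segment one (H, W, C)-layout tile pair."""
        rgb_b = np.ascontiguousarray(np.moveaxis(rgb, -1, 0))[None]
        ms_b = np.ascontiguousarray(np.moveaxis(ms, -1, 0))[None]
        logits = self(Tensor(rgb_b), Tensor(ms_b)).data[0]      # (2, H, W)
        # strict inequality: ties break toward background (class 0)
        mask = (logits[1] > logits[0]).astype(np.uint8)
        probs = _softmax_np(logits, axis=0)
        return SegmentationOutput(logits=np.moveaxis(logits, 0, -1),
                                  mask=mask,
                                  probabilities=np.moveaxis(probs, 0, -1))

    def predict_mask(self, rgb: np.ndarray, ms: np.ndarray) -> np.ndarray:
        return self.predict(rgb, ms).mask


class CrownFusionNet(nn.Module, _PredictMixin):
    """Dual-branch encoder + cross-modal fusion + attention decoder."""

    def __init__(self, config: ModelConfig):
        config.encoder.validate()
        config.decoder.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc_rgb = config.encoder if config.encoder.in_channels == 3 else \
            EncoderConfig(**{**asdict(config.encoder), "in_channels": 3})
        enc_ms = EncoderConfig(**{**asdict(config.encoder), "in_channels": 4})
        self.rgb_encoder = BranchEncoder(enc_rgb, rng, branch="rgb")
        self.ms_encoder = BranchEncoder(enc_ms, rng, branch="ms",
                                        expose=("feat4", "feat5"))
        widths = enc_rgb.widths
        channels = {"feat4": widths[3], "feat5": widths[4]}
        self.cif = CIF(channels, config.fusion, rng=rng)
        self.decoder = Decoder(widths, config.decoder, rng=rng)

    def forward(self, rgb: Tensor, ms: Tensor) -> Tensor:
        if rgb.shape[2:] != ms.shape[2:]:
            raise ValueError(f"modalities are not co-registered: "
                             f"{rgb.shape[2:]} vs {ms.shape[2:]}")
        rgb_pyr = self.rgb_encoder(rgb)
        ms_pyr = self.ms_encoder(ms)
        fused = self.cif(rgb_pyr, ms_pyr)
        return self.decoder(fused["feat5"], fused["feat4"], rgb_pyr["feat3"],
                            rgb_pyr["feat2"], rgb_pyr["feat1"])

    def fusion_weights(self) -> dict:
        return self.cif.fusion_weights()


class SingleModalityNet(nn.Module, _PredictMixin):
    """Identical architecture driven by one modality; fusion is bypassed.

    For ``mode='ms'`` the shallow skip path (the auxiliary half-resolution
    block and the backbone's early stages) runs on the MS input itself.
    """

    def __init__(self, config: ModelConfig, mode: str):
        if mode not in ("rgb", "ms"):
            raise ValueError("mode must be 'rgb' or 'ms'")
        self.mode = mode
        self.config = config
        rng = np.random.default_rng(config.seed)
        in_ch = 3 if mode == "rgb" else 4
        enc = EncoderConfig(**{**asdict(config.encoder), "in_channels": in_ch})
        self.encoder = BranchEncoder(enc, rng, branch=mode)
        self.decoder = Decoder(enc.widths, config.decoder, rng=rng)

    def forward(self, rgb: Tensor, ms: Tensor) -> Tensor:
        x = rgb if self.mode == "rgb" else ms
        pyr = self.encoder(x)
        return self.decoder(pyr["feat5"], pyr["feat4"], pyr["feat3"],
                            pyr["feat2"], pyr["feat1"])


def build_model(config: ModelConfig | None = None) -> CrownFusionNet:
    return CrownFusionNet(config or ModelConfig())


def build_single_modality_variant(config: ModelConfig, mode: str
                                  ) -> SingleModalityNet:
    return SingleModalityNet(config, mode)
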