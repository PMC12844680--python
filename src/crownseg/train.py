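"""Training engine: cross-entropy, Adam, cosine-annealed LR, early stopping.

The recipe follows the standard multimodal-segmentation setup: Adam
(beta1=0.9, beta2=0.999, weight decay 1e-4) at an initial learning rate of
1e-4 annealed cosinely to 1e-6 over the epoch budget, batch size 4, plain
two-class cross-entropy on the logits, and early stopping when the
validation mean IoU fails to improve on the best-so-far value for
``patience`` consecutive epochs.  The schedule is stepped per epoch.

Everything is seeded; with ``amp_enabled`` off (the default — this engine
computes in float32 throughout, so the flag is accepted for config
compatibility but changes nothing) two runs with equal seeds produce
identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import metrics as M
from . import nn
from .nn.tensor import Tensor
from .pipeline import augment_sample
from .synthetic import MultimodalSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cosine_lr",
    "train_model",
    "evaluate_miou",
    "save_checkpoint",
    "load_checkpoint",
    "samples_to_batch",
]


@dataclass
class TrainConfig:
    lr_init: float = 1e-4
    lr_min: float = 1e-6
    epochs: int = 200
    batch_size: int = 4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    patience: int = 5
    amp_enabled: bool = False
    seed: int = 0
    checkpoint_dir: str | None = None
    class_weights: tuple | None = None      # optional CE weights (bg, crown)
    augment_ops: tuple | None = None        # on-the-fly op names, e.g. ("hflip",)
    ms_noise: bool = False                  # replace MS input with pure noise

    def validate(self) -> None:
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.epochs < 1 or self.patience < 1 or self.batch_size < 1:
            raise ValueError("epochs, patience, and batch_size must be >= 1")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # dicts: epoch, loss, miou, lr
    best_epoch: int = 0
    best_val_miou: float = float("-inf")
    stop_reason: str = "completed"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


def cosine_lr(epoch: int, total_epochs: int, lr_init: float,
              lr_min: float) -> float:
    """Cosine annealing: lr_init at epoch 0 down to lr_min at total_epochs."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return lr_min + 0.5 * (lr_init - lr_min) * (
        1.0 + np.cos(np.pi * epoch / total_epochs))


def samples_to_batch(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (B,3,H,W) rgb, (B,4,H,W) ms, (B,H,W) int labels."""
    rgb = np.stack([np.moveaxis(s.rgb, -1, 0) for s in samples])
    ms = np.stack([np.moveaxis(s.ms, -1, 0) for s in samples])
    labels = np.stack([s.mask.astype(np.int64) for s in samples])
    return rgb.astype(np.float32), ms.astype(np.float32), labels


def evaluate_miou(model, samples, batch_size: int = 4) -> float:
    """Pooled two-class mean IoU of model predictions over ``samples``."""
    pooled = M.ConfusionCounts(0, 0, 0, 0)
    samples = list(samples)
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        rgb, ms, labels = samples_to_batch(chunk)
        logits = model(Tensor(rgb), Tensor(ms)).data
        pred = (logits[:, 1] > logits[:, 0]).astype(np.uint8)
        pooled = pooled + M.confusion(pred, labels.astype(np.uint8))
    return M.mean_iou(M.background_counts(pooled), pooled)


def _maybe_augment(sample: MultimodalSample, ops, rng) -> MultimodalSample:
    if not ops:
        return sample
    # choose one op or identity, uniformly
    k = int(rng.integers(0, len(ops) + 1))
    if k == 0:
        return sample
    op = ops[k - 1]
    seed = int(rng.integers(0, 2 ** 31))
    if op == "rot90":
        return augment_sample(sample, ("rot90", {"k": int(rng.integers(1, 4))}))
    return augment_sample(sample, (op,), seed=seed)


def train_model(model, train_samples, val_samples, config: TrainConfig
                ) -> tuple[dict, TrainHistory]:
    """Optimize ``model``; returns (best-mIoU state dict, history)."""
    config.validate()
    train_samples = list(train_samples)
    val_samples = list(val_samples)
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr_init,
                  betas=(config.beta1, config.beta2),
                  weight_decay=config.weight_decay)
    cw = None if config.class_weights is None else np.asarray(
        config.class_weights, dtype=np.float32)

    history = TrainHistory()
    best_state: dict = model.state_dict()
    stall = 0
    for epoch in range(1, config.epochs + 1):
        opt.lr = cosine_lr(epoch - 1, config.epochs, config.lr_init,
                           config.lr_min)
        order = rng.permutation(len(train_samples))
        losses = []
        for i in range(0, len(order), config.batch_size):
            chunk = [train_samples[j] for j in order[i:i + config.batch_size]]
            chunk = [_maybe_augment(s, config.augment_ops, rng) for s in chunk]
            rgb, ms, labels = samples_to_batch(chunk)
            if config.ms_noise:
                ms = rng.uniform(0.0, 1.0, ms.shape).astype(np.float32)
            opt.zero_grad()
            logits = model(Tensor(rgb), Tensor(ms))
            loss = nn.softmax_cross_entropy(logits, labels, class_weights=cw)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_miou = evaluate_miou(model, val_samples, config.batch_size)
        history.epochs.append({"epoch": epoch,
                               "train_loss": float(np.mean(losses)),
                               "val_miou": float(val_miou),
                               "lr": float(opt.lr)})
        if val_miou > history.best_val_miou:
            history.best_val_miou = float(val_miou)
            history.best_epoch = epoch
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                history.stop_reason = "early-stopped"
                break

    return best_state, history


def save_checkpoint(path, model, config: TrainConfig | None = None,
                    history: TrainHistory | None = None,
                    state: dict | None = None) -> None:
    """npz weights + JSON sidecar with config snapshot and history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **(state if state is not None else model.state_dict()))
    side = {"model_config": model.config.to_dict()
            if hasattr(model.config, "to_dict") else None}
    if config is not None:
        side["train_config"] = asdict(config)
    if history is not None:
        side["history"] = {"epochs": history.epochs,
                           "best_epoch": history.best_epoch,
                           "best_val_miou": history.best_val_miou,
                           "stop_reason": history.stop_reason}
    if hasattr(model, "fusion_weights"):
        side["fusion_weights"] = model.fusion_weights()
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh, indent=2, default=float)


def load_checkpoint(path, model) -> dict:
    """Load npz weights into ``model``; returns the JSON sidecar if present."""
    path = Path(path)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}
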