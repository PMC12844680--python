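"""Reference experiment protocols on synthetic scenes.

These bundle the package's standard desk-scale studies so that tests, the
command line, and reporting scripts all run the *same* procedures:

* :func:`overfit_protocol` — memorization sanity check: a reduced-width
  model must drive training crown IoU above a threshold on a tiny fixture
  within a step budget;
* :func:`modality_protocol` — the three-way input ablation (RGB-only,
  MS-only, fused) on scenes where half the crowns are separable only
  spectrally and half only by color;
* :func:`adaptivity_protocol` — trains with the MS input replaced by pure
  noise and reports how the learnable fusion weights (alpha for RGB, beta
  for MS) move away from their initialization.

Desk-scale settings (the package's small-compute envelope): reduced model =
quarter width with single-block stages and CBAM reduction 4; overfit
fixture = 8 tiles of 128 x 128; ablation and adaptivity runs use 96 x 96
tiles whose crowns span several cells of the deepest feature grids.  These
protocols use Adam at lr 5e-3 — the usual small-model setting — rather
than the full-scale training recipe in :mod:`crownseg.train`, whose
defaults mirror the production configuration; see each protocol's
docstring for its loss/weighting choices.
"""

from __future__ import annotations

import numpy as np

from . import metrics as M
from . import nn
from .nn.tensor import Tensor
from .decoder import DecoderConfig
from .encoder import EncoderConfig
from .model import (
    ModelConfig,
    build_model,
    build_single_modality_variant,
)
from .synthetic import SceneSpec, generate_dataset
from .train import TrainConfig, samples_to_batch, train_model

__all__ = [
    "overfit_protocol",
    "modality_protocol",
    "adaptivity_protocol",
    "OVERFIT_SPEC",
    "ABLATION_SPEC",
    "ADAPTIVITY_SPEC",
]

#: 128-px overfit fixture family.  As everywhere in these protocols, crowns
#: span multiple cells of the deepest feature grids (stride 16/32) — the
#: size regime the deep-level fusion operates in on full-size UAV tiles.
OVERFIT_SPEC = SceneSpec(height_px=128, width_px=128, n_crowns=3,
                         crown_radius_range=(16, 28), frac_ms_cued=0.5,
                         frac_shadowed=0.33, n_distractors=3)

#: Scene family for the modality ablation; half the crowns are spectrally
#: cued, half color-cued.  Crowns span several cells of the deepest feature
#: grids (stride 16/32), matching the size regime the deep-level fusion is
#: designed for.
ABLATION_SPEC = SceneSpec(height_px=96, width_px=96, n_crowns=2,
                          crown_radius_range=(16, 28), frac_ms_cued=0.5,
                          frac_shadowed=0.5, n_distractors=2)

#: Scene family for the fusion-weight adaptivity probe: denser clutter and
#: a larger spectral-only share keep the loss floor high when the MS input
#: is noise, which is what exerts pressure on the fusion weights.
ADAPTIVITY_SPEC = SceneSpec(height_px=96, width_px=96, n_crowns=3,
                            crown_radius_range=(12, 22), frac_ms_cued=0.5,
                            frac_shadowed=0.25, n_distractors=5)

_CLASS_WEIGHTS = np.array([1.0, 2.0], dtype=np.float32)


def _reduced_config(seed: int) -> ModelConfig:
    return ModelConfig(encoder=EncoderConfig.test_scale(),
                       decoder=DecoderConfig(cbam_reduction=4), seed=seed)


def _crown_iou(model, samples, batch_size: int = 4) -> float:
    pooled = M.ConfusionCounts(0, 0, 0, 0)
    for i in range(0, len(samples), batch_size):
        rgb, ms, labels = samples_to_batch(samples[i:i + batch_size])
        logits = model(Tensor(rgb), Tensor(ms)).data
        pred = (logits[:, 1] > logits[:, 0]).astype(np.uint8)
        pooled = pooled + M.confusion(pred, labels.astype(np.uint8))
    return M.iou(pooled)


def overfit_protocol(seed: int, max_steps: int = 300, target_iou: float = 90.0,
                     check_every: int = 10, n_samples: int = 8) -> dict:
    """Train a reduced model to memorize a tiny 128-px fixture.

    Returns the best training crown IoU observed, the step at which the
    target was first reached (or None), and the fixture size.
    """
    data_seed, model_seed = _derive(seed, 2)
    samples, _ = generate_dataset(OVERFIT_SPEC, n_samples, seed=data_seed)
    model = build_model(_reduced_config(model_seed))
    opt = nn.Adam(model.parameters(), lr=5e-3, weight_decay=1e-4)
    rng = np.random.default_rng(data_seed)
    step, best_iou, reached_at = 0, 0.0, None
    while step < max_steps:
        order = rng.permutation(len(samples))
        for i in range(0, len(order), 4):
            chunk = [samples[j] for j in order[i:i + 4]]
            rgb, ms, labels = samples_to_batch(chunk)
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(model(Tensor(rgb), Tensor(ms)),
                                            labels, class_weights=_CLASS_WEIGHTS)
            loss.backward()
            opt.step()
            step += 1
            if step % check_every == 0 or step == max_steps:
                iou = _crown_iou(model, samples)
                best_iou = max(best_iou, iou)
                if reached_at is None and iou >= target_iou:
                    reached_at = step
            if reached_at is not None or step >= max_steps:
                break
        if reached_at is not None:
            break
    return {"best_train_crown_iou": float(best_iou),
            "reached_at_step": reached_at,
            "steps_run": step,
            "n_samples": n_samples}


def modality_protocol(seed: int, n_train: int = 20, n_val: int = 12,
                      epochs: int = 50) -> dict:
    """Validation crown IoU of fused vs RGB-only vs MS-only models.

    All three variants share the reduced architecture and identical data
    (with flip/rotation augmentation, as in the full training recipe); only
    the input wiring differs.  Training uses plain cross-entropy — a crown
    class weight would bias all three variants toward blanket canopy
    prediction and mask the modality contrast — with a cosine-decayed
    learning rate, and each variant reports its validation crown IoU
    averaged over the last five epochs: a selection-free estimate (picking
    each model's luckiest checkpoint on a small validation set would
    systematically inflate the single-modality baselines).
    """
    from .train import _maybe_augment

    data_seed, model_seed = _derive(seed, 2)
    train, _ = generate_dataset(ABLATION_SPEC, n_train, seed=data_seed)
    val, _ = generate_dataset(ABLATION_SPEC, n_val, seed=data_seed + 1)
    config = _reduced_config(model_seed)
    aug_ops = ("hflip", "vflip", "rot90")
    out = {}
    for name, model in (
            ("fused", build_model(config)),
            ("rgb_only", build_single_modality_variant(config, "rgb")),
            ("ms_only", build_single_modality_variant(config, "ms"))):
        opt = nn.Adam(model.parameters(), lr=5e-3, weight_decay=1e-4)
        rng = np.random.default_rng(data_seed)
        tail_ious = []
        for epoch in range(epochs):
            opt.lr = 2e-4 + 0.5 * (5e-3 - 2e-4) * (
                1.0 + np.cos(np.pi * epoch / epochs))
            order = rng.permutation(n_train)
            for i in range(0, n_train, 4):
                chunk = [_maybe_augment(train[j], aug_ops, rng)
                         for j in order[i:i + 4]]
                rgb, ms, labels = samples_to_batch(chunk)
                opt.zero_grad()
                loss = nn.softmax_cross_entropy(model(Tensor(rgb), Tensor(ms)),
                                                labels)
                loss.backward()
                opt.step()
            if epoch >= epochs - 5:
                tail_ious.append(_crown_iou(model, val))
        out[f"{name}_val_crown_iou"] = float(np.mean(tail_ious))
    out["n_train"], out["n_val"] = n_train, n_val
    return out


def adaptivity_protocol(seed: int, n_train: int = 16, n_val: int = 4,
                        epochs: int = 60) -> dict:
    """Train with the MS input replaced by pure noise; report fusion weights.

    When one modality carries no signal, the learnable fusion weights should
    shift the balance toward the informative branch (beta below its
    initialization, alpha at or above beta).
    """
    data_seed, model_seed = _derive(seed, 2)
    train, _ = generate_dataset(ADAPTIVITY_SPEC, n_train, seed=data_seed)
    val, _ = generate_dataset(ADAPTIVITY_SPEC, n_val, seed=data_seed + 1)
    config = _reduced_config(model_seed)
    model = build_model(config)
    init = model.fusion_weights()
    tc = TrainConfig(lr_init=5e-3, lr_min=1e-5, epochs=epochs, batch_size=4,
                     patience=epochs, seed=data_seed, ms_noise=True,
                     class_weights=(1.0, 2.0))
    _best, _history = train_model(model, train, val, tc)
    # report the final (not best-checkpoint) weights: adaptation is the point
    final = model.fusion_weights()
    return {"init": init, "trained": final, "n_train": n_train}


def _derive(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
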