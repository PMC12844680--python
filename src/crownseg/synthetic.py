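"""Synthetic co-registered RGB + multispectral crown scenes.

Real UAV crown datasets are rarely shareable, so this module fabricates
paired tiles that reproduce the *structure* that makes multimodal fusion
worthwhile rather than the photometry of any particular forest:

* **ms-cued crowns** share the green RGB palette of distractor canopies and
  are separable only by elevated NIR / RedEdge reflectance;
* **rgb-cued crowns** are autumn-yellow in RGB but spectrally identical to
  distractors in all four narrow bands;
* **shadow fields** darken all bands multiplicatively;
* MS bands are blurred (emulating the lower spatial resolution of
  multispectral sensors) and then noised.

Crowns are superellipses with random axis ratio and rotation; their axes are
normalized so each crown's support area equals ``pi * ratio * r**2``, which
keeps coverage brute-force checkable.  Everything is driven by one seeded
``numpy.random.Generator``, so equal (spec, seed) gives bit-identical tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as _gamma_fn

__all__ = [
    "SceneSpec",
    "MultimodalSample",
    "SceneValidationError",
    "generate_sample",
    "generate_dataset",
    "write_sample",
    "read_sample",
    "MS_BANDS",
]

#: Multispectral band order used throughout the package.
MS_BANDS = ("red", "nir", "green", "rededge")

# Flat per-class band means (reflectance in [0, 1]).  RGB rows are (R, G, B);
# MS rows follow MS_BANDS.  Distractor canopies and ms-cued crowns share the
# RGB palette; rgb-cued crowns and distractors share the MS spectrum.
_PALETTE = {
    "background": {"rgb": (0.28, 0.24, 0.18), "ms": (0.28, 0.30, 0.24, 0.26)},
    "distractor": {"rgb": (0.10, 0.32, 0.12), "ms": (0.10, 0.45, 0.32, 0.28)},
    "ms_cued":    {"rgb": (0.10, 0.32, 0.12), "ms": (0.10, 0.85, 0.32, 0.60)},
    "rgb_cued":   {"rgb": (0.78, 0.66, 0.12), "ms": (0.10, 0.45, 0.32, 0.28)},
}


class SceneValidationError(ValueError):
    """A SceneSpec field violates its invariant; the message names the field."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene family."""

    height_px: int = 256
    width_px: int = 256
    n_crowns: int = 6
    crown_radius_range: tuple[float, float] = (12.0, 28.0)
    frac_ms_cued: float = 0.5
    frac_shadowed: float = 0.3
    n_distractors: int = 8
    noise_sigma: float = 0.02
    ms_blur_sigma: float = 1.5
    altitude_scale: float = 1.0
    #: per-blob brightness variation (fraction; applied to every canopy blob
    #: in all bands alike, so it carries no class information).  0 renders
    #: blobs individually anonymous, which is the harder regime for tests
    #: of generalization; small positive values emulate natural per-crown
    #: albedo differences.
    crown_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.height_px <= 0:
            raise SceneValidationError("height_px must be positive")
        if self.width_px <= 0:
            raise SceneValidationError("width_px must be positive")
        if self.n_crowns < 0:
            raise SceneValidationError("n_crowns must be non-negative")
        if self.n_distractors < 0:
            raise SceneValidationError("n_distractors must be non-negative")
        rmin, rmax = self.crown_radius_range
        if rmin > rmax:
            raise SceneValidationError("crown_radius_range min must be <= max")
        if rmax * self.altitude_scale >= min(self.height_px, self.width_px) / 2:
            raise SceneValidationError(
                "crown_radius_range max (after altitude_scale) must be below "
                "half the smaller image dimension")
        for name in ("frac_ms_cued", "frac_shadowed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SceneValidationError(f"{name} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise SceneValidationError("noise_sigma must be non-negative")
        if self.ms_blur_sigma < 0:
            raise SceneValidationError("ms_blur_sigma must be non-negative")
        if self.altitude_scale <= 0:
            raise SceneValidationError("altitude_scale must be positive")
        if not 0.0 <= self.crown_jitter < 1.0:
            raise SceneValidationError("crown_jitter must lie in [0, 1)")


@dataclass
class MultimodalSample:
    """One co-registered RGB / MS / mask triple."""

    rgb: np.ndarray          # (H, W, 3) float32 in [0, 1]
    ms: np.ndarray           # (H, W, 4) float32 in [0, 1], bands = MS_BANDS
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        h, w = self.mask.shape
        if self.rgb.shape != (h, w, 3) or self.ms.shape != (h, w, 4):
            raise ValueError("rgb/ms/mask spatial dimensions disagree")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _superellipse_support(h: int, w: int, cy: float, cx: float, a: float,
                          b: float, power: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy + 0.5) - cy
    dx = (xx + 0.5) - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (np.abs(u / a) ** power + np.abs(v / b) ** power) <= 1.0


def _area_factor(power: float) -> float:
    # area of |x/a|^p + |y/b|^p <= 1 is 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)
    return 4.0 * _gamma_fn(1.0 + 1.0 / power) ** 2 / _gamma_fn(1.0 + 2.0 / power)


def _sample_blob(rng: np.random.Generator, spec: SceneSpec,
                 placed: list[tuple[float, float, float]]) -> dict:
    """Draw one crown/distractor geometry, avoiding heavy overlap with ``placed``."""
    rmin, rmax = spec.crown_radius_range
    r = rng.uniform(rmin, rmax) * spec.altitude_scale
    ratio = rng.uniform(0.6, 1.0)
    power = rng.uniform(2.0, 4.0)
    theta = rng.uniform(0.0, np.pi)
    # normalize axes so the support area is exactly pi * ratio * r^2
    scale = np.sqrt(np.pi / _area_factor(power))
    a, b = r * scale, ratio * r * scale
    h, w = spec.height_px, spec.width_px
    lo_y, hi_y = r, max(h - r, r + 1e-3)
    lo_x, hi_x = r, max(w - r, r + 1e-3)
    cy = cx = None
    for _ in range(200):
        cy = rng.uniform(lo_y, hi_y)
        cx = rng.uniform(lo_x, hi_x)
        if all(np.hypot(cy - py, cx - px) >= 0.8 * (r + pr)
               for py, px, pr in placed):
            break
    placed.append((cy, cx, r))
    return {"cy": cy, "cx": cx, "a": a, "b": b, "power": power,
            "theta": theta, "r": r}


def generate_sample(spec: SceneSpec, seed: int | None = None) -> MultimodalSample:
    """Render one co-registered tile; equal (spec, seed) is bit-reproducible."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px

    rgb = np.empty((h, w, 3), dtype=np.float32)
    ms = np.empty((h, w, 4), dtype=np.float32)
    rgb[:] = _PALETTE["background"]["rgb"]
    ms[:] = _PALETTE["background"]["ms"]

    # smooth canopy texture field, later applied multiplicatively to every
    # band; being shared across blobs it textures crowns without giving any
    # single blob an identifiable brightness signature
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=max(4, h // 24))
    peak = np.abs(texture).max()
    if peak > 0:
        texture = texture / peak

    placed: list[tuple[float, float, float]] = []
    mask = np.zeros((h, w), dtype=np.uint8)

    def paint(kind: str, support: np.ndarray):
        jitter = np.float32(1.0 + rng.uniform(-spec.crown_jitter,
                                              spec.crown_jitter))
        rgb[support] = jitter * np.asarray(_PALETTE[kind]["rgb"], np.float32)
        ms[support] = jitter * np.asarray(_PALETTE[kind]["ms"], np.float32)

    # draw every blob geometry first under the shared rejection rule, then
    # assign classes by random permutation: placement statistics (position,
    # overlap, crowding) are exchangeable across classes, so geometry alone
    # carries no class information
    n_total = spec.n_distractors + spec.n_crowns
    geoms = [_sample_blob(rng, spec, placed) for _ in range(n_total)]
    n_ms_cued = int(round(spec.frac_ms_cued * spec.n_crowns))
    labels = (["distractor"] * spec.n_distractors
              + ["ms_cued"] * n_ms_cued
              + ["rgb_cued"] * (spec.n_crowns - n_ms_cued))
    labels = [labels[i] for i in rng.permutation(n_total)]

    # paint distractors first so targets overwrite them where they overlap
    distractor_mask = np.zeros((h, w), dtype=bool)
    distractor_centers = []
    crown_centers = []
    kind_masks = {"ms_cued": np.zeros((h, w), dtype=bool),
                  "rgb_cued": np.zeros((h, w), dtype=bool)}
    order = sorted(range(n_total), key=lambda i: labels[i] != "distractor")
    for i in order:
        geom, kind = geoms[i], labels[i]
        support = _superellipse_support(h, w, geom["cy"], geom["cx"], geom["a"],
                                        geom["b"], geom["power"], geom["theta"])
        paint(kind, support)
        if kind == "distractor":
            distractor_mask |= support
            distractor_centers.append((geom["cy"], geom["cx"], geom["r"]))
        else:
            mask[support] = 1
            kind_masks[kind] |= support
            distractor_mask &= ~support
            crown_centers.append((geom["cy"], geom["cx"], geom["r"], kind))

    # shared canopy texture, multiplicative in all bands
    field = (1.0 + 0.08 * texture)[:, :, None].astype(np.float32)
    rgb *= field
    ms *= field

    def cast_shadow(cy, cx, r):
        off_y = cy + rng.uniform(-0.5, 0.5) * r
        off_x = cx + rng.uniform(-0.5, 0.5) * r
        shadow = _superellipse_support(h, w, off_y, off_x, 1.5 * r, 1.5 * r,
                                       2.0, 0.0)
        factor = np.float32(rng.uniform(0.3, 0.7))
        rgb[shadow] *= factor
        ms[shadow] *= factor

    # multiplicative shadow blobs, i.i.d. per blob at the same rate for
    # target crowns and distractor canopies: with independent draws the
    # shadow pattern carries no class information (fixed per-tile shadow
    # counts would let shadow status of one blob inform the class of
    # another)
    for cy, cx, r, _kind in crown_centers:
        if rng.random() < spec.frac_shadowed:
            cast_shadow(cy, cx, r)
    for cy, cx, r in distractor_centers:
        if rng.random() < spec.frac_shadowed:
            cast_shadow(cy, cx, r)

    # photometric degradation: MS is blurred then both modalities are noised
    if spec.ms_blur_sigma > 0:
        for band in range(4):
            ms[:, :, band] = gaussian_filter(ms[:, :, band], spec.ms_blur_sigma)
    if spec.noise_sigma > 0:
        rgb += rng.normal(0.0, spec.noise_sigma, rgb.shape).astype(np.float32)
        ms += rng.normal(0.0, spec.noise_sigma, ms.shape).astype(np.float32)
    np.clip(rgb, 0.0, 1.0, out=rgb)
    np.clip(ms, 0.0, 1.0, out=ms)

    meta = {"spec": asdict(spec), "seed": int(seed),
            "distractor_mask": distractor_mask,
            "kind_masks": kind_masks,
            "crown_kinds": [k for *_xy, k in crown_centers]}
    sample = MultimodalSample(rgb=rgb.astype(np.float32),
                              ms=ms.astype(np.float32), mask=mask, meta=meta)
    sample.validate()
    return sample


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-sample seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_dataset(spec: SceneSpec, n_samples: int, seed: int
                     ) -> tuple[list[MultimodalSample], pd.DataFrame]:
    """Generate ``n_samples`` tiles plus a manifest (id, seed, coverage)."""
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    spec.validate()
    seeds = derive_seeds(seed, n_samples)
    samples, rows = [], []
    for i, s in enumerate(seeds):
        sample = generate_sample(spec, s)
        sample.meta["id"] = f"tile_{i:04d}"
        samples.append(sample)
        rows.append({"id": sample.meta["id"], "seed": s,
                     "coverage": float(sample.mask.mean())})
    manifest = pd.DataFrame(rows, columns=["id", "seed", "coverage"])
    return samples, manifest


# -- on-disk layout: RGB png, 4-band tiff, mask png ------------------------

def write_sample(sample: MultimodalSample, directory, stem: str) -> dict:
    """Write rgb as 8-bit PNG, ms as 4-band float32 TIFF, mask as {0,255} PNG."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rgb": directory / f"{stem}_rgb.png",
        "ms": directory / f"{stem}_ms.tif",
        "mask": directory / f"{stem}_mask.png",
    }
    Image.fromarray((sample.rgb * 255.0 + 0.5).astype(np.uint8)).save(paths["rgb"])
    tifffile.imwrite(paths["ms"], np.moveaxis(sample.ms, -1, 0),
                     photometric="minisblack")  # band-first
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(paths["mask"])
    return {k: str(v) for k, v in paths.items()}


def read_sample(directory, stem: str) -> MultimodalSample:
    from pathlib import Path
    directory = Path(directory)
    rgb = np.asarray(Image.open(directory / f"{stem}_rgb.png"),
                     dtype=np.float32) / 255.0
    ms = np.moveaxis(tifffile.imread(directory / f"{stem}_ms.tif"), 0, -1)
    mask = (np.asarray(Image.open(directory / f"{stem}_mask.png")) > 127
            ).astype(np.uint8)
    sample = MultimodalSample(rgb=rgb, ms=ms.astype(np.float32), mask=mask,
                              meta={"id": stem})
    sample.validate()
    return sample
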