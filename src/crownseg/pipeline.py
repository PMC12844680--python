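"""Dataset construction: tiling, annotation rasterization, screening,
augmentation, and the train/validation split.

The workflow mirrors how UAV orthomosaics are turned into training tiles:
a sliding window with fractional overlap crops fixed-size patches (a final
window is clamped to the image edge so no pixel is lost), polygon crown
annotations are rasterized to binary masks, tiles without any crown pixels
are screened out, geometric augmentation is applied jointly to imagery and
mask, and tile ids are split into train/validation subsets.

Conventions: 0-based (row, col) pixel indexing; windows are half-open
``[start, start + window)``; tile origins are (x0, y0) = (col, row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import rescale, resize

from .synthetic import MultimodalSample

__all__ = [
    "TileGrid",
    "AnnotationSet",
    "plan_tiles",
    "extract_tiles",
    "rasterize_polygons",
    "screen_tiles",
    "augment_sample",
    "split_samples",
    "read_labelme",
    "AUGMENTATION_OPS",
]


@dataclass(frozen=True)
class TileGrid:
    window_px: int
    stride_px: int
    origins: tuple          # ordered ((x0, y0), ...), row-major
    source_size: tuple      # (width, height)


@dataclass
class AnnotationSet:
    """Polygon annotations: list of (label, (n, 2) float array of (x, y))."""

    polygons: list
    image_size: tuple       # (width, height)

    def validate(self) -> None:
        for label, verts in self.polygons:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ValueError(
                    f"polygon '{label}' is degenerate: needs >=3 (x, y) vertices")


def _axis_starts(dim: int, window: int, stride: int) -> list[int]:
    starts, s = [], 0
    while s + window <= dim:
        starts.append(s)
        s += stride
    if starts[-1] + window < dim:       # clamp a final window to the edge
        starts.append(dim - window)
    return starts


def plan_tiles(width: int, height: int, window_px: int = 640,
               overlap_frac: float = 0.25) -> TileGrid:
    """Row-major sliding-window grid with fractional overlap.

    ``stride = round(window * (1 - overlap_frac))``; a final clamped origin
    is appended per axis whenever the regular stride would leave a strip of
    pixels uncovered.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    if window_px > min(width, height):
        raise ValueError(
            f"window_px={window_px} exceeds source size {width}x{height}")
    stride = int(round(window_px * (1.0 - overlap_frac)))
    xs = _axis_starts(width, window_px, stride)
    ys = _axis_starts(height, window_px, stride)
    origins = tuple((x, y) for y in ys for x in xs)
    return TileGrid(window_px=window_px, stride_px=stride, origins=origins,
                    source_size=(width, height))


def extract_tiles(stack: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Crop every grid window from an (H, W[, C]) raster, band order preserved."""
    h, w = stack.shape[:2]
    if (w, h) != grid.source_size:
        raise ValueError(f"raster size {(w, h)} does not match grid "
                         f"source_size {grid.source_size}")
    win = grid.window_px
    return [stack[y0:y0 + win, x0:x0 + win].copy() for x0, y0 in grid.origins]


def _points_in_polygon(px: np.ndarray, py: np.ndarray,
                       verts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) point-in-polygon test."""
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = verts[-1]
    for x2, y2 in verts:
        crosses = (y1 > py) != (y2 > py)
        if crosses.any():
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        x1, y1 = x2, y2
    return inside


def rasterize_polygons(ann: AnnotationSet, height: int, width: int,
                       target_labels=None) -> np.ndarray:
    """Binary mask: 1 iff the pixel center lies inside >=1 target polygon.

    Pixel centers sit at (col + 0.5, row + 0.5); the fill rule is even-odd;
    overlapping polygons union.
    """
    ann.validate()
    yy, xx = np.mgrid[0:height, 0:width]
    px = (xx + 0.5).astype(float).ravel()
    py = (yy + 0.5).astype(float).ravel()
    mask = np.zeros(height * width, dtype=bool)
    for label, verts in ann.polygons:
        if target_labels is not None and label not in target_labels:
            continue
        mask |= _points_in_polygon(px, py, np.asarray(verts, dtype=float))
    return mask.reshape(height, width).astype(np.uint8)


def screen_tiles(masks, min_positive_frac: float = 0.0) -> list[int]:
    """Indices of masks whose positive fraction exceeds ``min_positive_frac``."""
    if not 0.0 <= min_positive_frac <= 1.0:
        raise ValueError("min_positive_frac must lie in [0, 1]")
    kept = []
    for i, m in enumerate(masks):
        if float(np.asarray(m).mean()) > min_positive_frac:
            kept.append(i)
    return kept


def _joint_geometric(sample: MultimodalSample, img_fn, mask_fn) -> MultimodalSample:
    rgb = img_fn(sample.rgb).astype(np.float32)
    ms = img_fn(sample.ms).astype(np.float32)
    mask = mask_fn(sample.mask)
    mask = (np.asarray(mask) > 0.5).astype(np.uint8)
    out = MultimodalSample(rgb=rgb, ms=ms, mask=mask, meta=dict(sample.meta))
    out.validate()
    return out


def _scale_center_crop(sample: MultimodalSample, factor: float) -> MultimodalSample:
    if factor < 1.0:
        raise ValueError("scale_center_crop factor must be >= 1")
    h, w = sample.mask.shape

    def crop(arr):
        hh, ww = arr.shape[:2]
        top, left = (hh - h) // 2, (ww - w) // 2
        return arr[top:top + h, left:left + w]

    def img_fn(arr):
        big = rescale(arr, factor, order=1, channel_axis=-1,
                      preserve_range=True, anti_aliasing=False)
        return crop(big)

    def mask_fn(arr):
        big = rescale(arr.astype(float), factor, order=0,
                      preserve_range=True, anti_aliasing=False)
        return crop(big)

    return _joint_geometric(sample, img_fn, mask_fn)


def _random_crop_resize(sample: MultimodalSample, frac: float,
                        rng: np.random.Generator) -> MultimodalSample:
    if not 0.0 < frac <= 1.0:
        raise ValueError("random_crop_resize frac must lie in (0, 1]")
    h, w = sample.mask.shape
    ch, cw = max(1, int(round(frac * h))), max(1, int(round(frac * w)))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))

    def img_fn(arr):
        return resize(arr[top:top + ch, left:left + cw], (h, w) + arr.shape[2:],
                      order=1, preserve_range=True, anti_aliasing=False)

    def mask_fn(arr):
        return resize(arr[top:top + ch, left:left + cw].astype(float), (h, w),
                      order=0, preserve_range=True, anti_aliasing=False)

    return _joint_geometric(sample, img_fn, mask_fn)


AUGMENTATION_OPS = ("rot90", "hflip", "vflip", "scale_center_crop",
                    "random_crop_resize")


def augment_sample(sample: MultimodalSample, op_spec, seed: int = 0
                   ) -> MultimodalSample:
    """Apply one named geometric augmentation jointly to rgb, ms, and mask.

    ``op_spec`` is ``(name,)`` or ``(name, params_dict)`` with name drawn
    from :data:`AUGMENTATION_OPS`.  Images are interpolated bilinearly, the
    mask with nearest neighbor, so binarity and co-registration survive;
    output size always equals input size.
    """
    name = op_spec[0]
    params = op_spec[1] if len(op_spec) > 1 else {}
    if name == "rot90":
        k = int(params.get("k", 1))
        return _joint_geometric(sample,
                                lambda a: np.rot90(a, k, axes=(0, 1)).copy(),
                                lambda a: np.rot90(a, k, axes=(0, 1)).copy())
    if name == "hflip":
        return _joint_geometric(sample, lambda a: a[:, ::-1].copy(),
                                lambda a: a[:, ::-1].copy())
    if name == "vflip":
        return _joint_geometric(sample, lambda a: a[::-1].copy(),
                                lambda a: a[::-1].copy())
    if name == "scale_center_crop":
        return _scale_center_crop(sample, float(params.get("factor", 1.25)))
    if name == "random_crop_resize":
        rng = np.random.default_rng(seed)
        return _random_crop_resize(sample, float(params.get("frac", 0.8)), rng)
    raise ValueError(f"unknown augmentation op '{name}'; "
                     f"expected one of {AUGMENTATION_OPS}")


def split_samples(ids, train_frac: float = 0.8, seed: int = 0):
    """Deterministic shuffled partition; |train| = round-half-up(train_frac * n).

    Held-out test data never passes through this split — it is supplied as a
    separate source.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot split an empty id list")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_frac * len(ids) + 0.5))
    shuffled = [ids[i] for i in order]
    return shuffled[:n_train], shuffled[n_train:]


def read_labelme(path) -> AnnotationSet:
    """Read a LabelMe-style JSON file (shapes with label + points)."""
    with open(path) as fh:
        doc = json.load(fh)
    polygons = [(shape["label"], np.asarray(shape["points"], dtype=float))
                for shape in doc.get("shapes", [])]
    size = (int(doc.get("imageWidth", 0)), int(doc.get("imageHeight", 0)))
    ann = AnnotationSet(polygons=polygons, image_size=size)
    ann.validate()
    return ann


def tile_manifest(grid: TileGrid, kept: list[int], splits: dict,
                  source_id: str = "source") -> pd.DataFrame:
    """Tile bookkeeping table: id, source, origin, kept flag, split name."""
    rows = []
    for i, (x0, y0) in enumerate(grid.origins):
        tile_id = f"{source_id}_t{i:04d}"
        rows.append({
            "tile_id": tile_id,
            "source_id": source_id,
            "x0": x0,
            "y0": y0,
            "kept": i in kept,
            "split": splits.get(tile_id, ""),
        })
    return pd.DataFrame(rows)
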