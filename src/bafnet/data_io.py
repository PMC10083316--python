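"""Image/mask I/O, LabelMe polygon rasterization, and dataset bookkeeping.

Masks are single-channel PNGs storing literal {0, 1} values (a reader
tolerance also accepts {0, 255} and normalises).  Polygon rasterization uses
pixel centres at (col + 0.5, row + 0.5) with the even-odd rule, so a pixel is
foreground iff its centre lies inside an odd number of polygon boundaries
(half-open: boundary-aligned axis edges exclude the outer row/column).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LabelMeAnnotation",
    "DatasetSplit",
    "labelme_to_mask",
    "read_labelme",
    "polygon_mask",
    "load_image",
    "load_mask",
    "save_mask",
    "load_pair",
    "split_dataset",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "split", "class")

#: train/val/test fractions matching the published dataset proportions
DEFAULT_FRACTIONS = (0.733, 0.133, 0.134)


@dataclass
class LabelMeAnnotation:
    """image_size = (height, width); polygons = [(label, [(x, y), ...]), ...]."""

    image_size: tuple
    polygons: list

    def __post_init__(self):
        for label, verts in self.polygons:
            if len(verts) < 3:
                raise ValueError(f"polygon {label!r} has fewer than 3 vertices")


@dataclass(frozen=True)
class DatasetSplit:
    train: list
    val: list
    test: list

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split parts must be disjoint")


# ------------------------------------------------------------------ polygons
def polygon_mask(vertices, shape) -> np.ndarray:
    """Even-odd rasterization of one polygon onto an (H, W) grid.

    A vectorised crossing-number test at every pixel centre.  Vertices are
    (x, y) in pixel coordinates; out-of-bounds vertices are used as-is (the
    raster simply clips).
    """
    H, W = shape
    v = np.asarray(vertices, dtype=float)
    cx = np.arange(W) + 0.5
    cy = np.arange(H) + 0.5
    px, py = np.meshgrid(cx, cy)  # H, W
    inside = np.zeros((H, W), dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 == y2:
            continue
        cond = (py >= min(y1, y2)) & (py < max(y1, y2))
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
    return inside.astype(np.uint8)


def _is_self_intersecting(vertices) -> bool:
    from shapely.geometry import Polygon

    try:
        return not Polygon(vertices).is_valid
    except Exception:
        return True


def labelme_to_mask(ann: LabelMeAnnotation) -> np.ndarray:
    """Union of all annotated polygons as a {0,1} uint8 raster."""
    mask = np.zeros(ann.image_size, dtype=np.uint8)
    if not ann.polygons:
        warnings.warn("annotation has no polygons; returning an empty mask",
                      stacklevel=2)
        return mask
    for label, verts in ann.polygons:
        if _is_self_intersecting(verts):
            warnings.warn(
                f"polygon {label!r} is self-intersecting; even-odd fill applied",
                stacklevel=2,
            )
        mask |= polygon_mask(verts, ann.image_size)
    return mask


def read_labelme(path) -> LabelMeAnnotation:
    """Parse a LabelMe JSON file ('shapes' with 'points', 0-based x=col, y=row)."""
    doc = json.loads(Path(path).read_text())
    size = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    polys = [
        (shape.get("label", ""), [tuple(p) for p in shape["points"]])
        for shape in doc.get("shapes", [])
        if shape.get("shape_type", "polygon") == "polygon"
    ]
    return LabelMeAnnotation(size, polys)


# ------------------------------------------------------------------- images
def load_image(path, target_size=None) -> np.ndarray:
    """RGB image as float32 (3, H, W) scaled to [0, 1]; bilinear resize."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if target_size is not None:
            im = im.resize((target_size, target_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_mask(path, target_size=None) -> np.ndarray:
    """Binary mask as uint8 (1, H, W); accepts {0,1} or {0,255} PNGs."""
    with Image.open(path) as im:
        im = im.convert("L")
        if target_size is not None:
            im = im.resize((target_size, target_size), Image.NEAREST)
        arr = np.asarray(im, dtype=np.uint8)
    values = np.unique(arr)
    if np.isin(values, (0, 255)).all():
        arr = (arr > 0).astype(np.uint8)
    elif not np.isin(values, (0, 1)).all():
        raise ValueError(f"mask {path} holds values outside {{0,1}}/{{0,255}}")
    return arr[None]


def save_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a literal-valued single-channel 8-bit PNG."""
    arr = np.asarray(mask, dtype=np.uint8)
    arr = arr[0] if arr.ndim == 3 else arr
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    Image.fromarray(arr, mode="L").save(path)


def load_pair(image_path, mask_path, target_size: int | None = 512):
    """Load an (image, mask) pair resized to target_size (bilinear / nearest)."""
    image = load_image(image_path, target_size)
    mask = load_mask(mask_path, target_size)
    if image.shape[1:] != mask.shape[1:]:
        raise ValueError(
            f"image {image.shape[1:]} and mask {mask.shape[1:]} sizes differ"
        )
    return image, mask


# -------------------------------------------------------------------- splits
def split_dataset(ids, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> DatasetSplit:
    """Seeded shuffle then partition into train/val/test.

    Sizes are round(n*f_train) and round(n*f_val); the test set takes the
    remainder, which reproduces the published 1015/184/186 split of 1385
    samples at the default fractions.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = round(n * fractions[0])
    n_val = round(n * fractions[1])
    return DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
    )


# ----------------------------------------------------------------- manifests
def write_manifest(df: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
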