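"""Synthetic leaf-image generator.

Produces image/mask pairs that emulate the statistical structure of field
photographs of single pepper leaves: one dominant star-convex leaf with a
lobed boundary, vein lines, optional brown disease spots, composited over a
plain, cluttered, or soil-like background with an optional illumination
gradient.  The star-convex boundary r(theta) = r0 * (1 + a*sin(n*theta+phi))
guarantees a simple region whose area has a closed form, so the mask can be
checked analytically.

These images are deliberately schematic: they are fixtures for exercising
the segmentation pipeline, not stand-ins for the intensity statistics of
real leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import save_mask, write_manifest

__all__ = ["LeafGenConfig", "generate_leaf", "generate_dataset",
           "LEAF_HSV_BAND", "SPOT_HSV_BAND"]

#: HSV bands (h in [0,1]) the leaf body and disease spots are drawn from.
LEAF_HSV_BAND = {"h": (0.22, 0.38), "s": (0.45, 0.85), "v": (0.35, 0.75)}
SPOT_HSV_BAND = {"h": (0.05, 0.09), "s": (0.55, 0.85), "v": (0.25, 0.45)}


@dataclass(frozen=True)
class LeafGenConfig:
    """image_size in pixels; n_lobes boundary lobes; lobe_amplitude as a
    fraction of the base radius (in [0, 0.5)); spot_density = expected spots
    per leaf; radius_frac = base radius r0 as a fraction of image size."""

    image_size: int = 512
    n_lobes: int = 5
    lobe_amplitude: float = 0.08
    spot_density: float = 6.0
    background: str = "clutter"
    illumination_gradient: bool = True
    radius_frac: float = 0.30
    center_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.lobe_amplitude < 0.5:
            raise ValueError("lobe_amplitude must lie in [0, 0.5)")
        if self.background not in ("plain", "clutter", "soil"):
            raise ValueError("background must be plain, clutter, or soil")


def _hsv_to_rgb(h, s, v):
    h = (h % 1.0) * 6.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    table = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    r = np.choose(i, [c[0] for c in table])
    g = np.choose(i, [c[1] for c in table])
    b = np.choose(i, [c[2] for c in table])
    return np.stack([r, g, b])


def _band_sample(rng, band):
    return tuple(rng.uniform(*band[k]) for k in ("h", "s", "v"))


def _background(rng, size, kind):
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if kind == "plain":
        base = np.full((3, size, size), 0.55)
        base += rng.normal(0, 0.01, (3, size, size))
    elif kind == "soil":
        h = 0.07 + 0.02 * rng.standard_normal()
        base = _hsv_to_rgb(
            np.full((size, size), h),
            np.full((size, size), 0.5),
            0.35 + 0.1 * _smooth_noise(rng, size, 8),
        )
    else:  # clutter: overlapping soft blobs of varied hue
        base = np.full((3, size, size), 0.45)
        for _ in range(12):
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(size / 12, size / 4)
            hue = rng.uniform(0, 1)
            color = _hsv_to_rgb(np.array([[hue]]), np.array([[0.4]]),
                                np.array([[rng.uniform(0.3, 0.8)]]))[:, 0, 0]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            w = np.exp(-d2 / (2 * (r / 2) ** 2))
            base = base * (1 - w) + color[:, None, None] * w
        base += rng.normal(0, 0.02, (3, size, size))
    return np.clip(base, 0, 1)


def _smooth_noise(rng, size, cells):
    coarse = rng.random((cells, cells))
    rep = int(np.ceil(size / cells))
    return np.kron(coarse, np.ones((rep, rep)))[:size, :size]


def leaf_boundary_radius(theta, r0, n_lobes, amplitude, phase):
    return r0 * (1.0 + amplitude * np.sin(n_lobes * theta + phase))


def generate_leaf(cfg: LeafGenConfig):
    """One (image, mask) pair; image float32 (3,S,S) in [0,1], mask uint8 (S,S)."""
    rng = np.random.default_rng(cfg.seed)
    S = cfg.image_size
    r0 = cfg.radius_frac * S
    phase = rng.uniform(0, 2 * np.pi)
    jitter = cfg.center_jitter * S
    cy = S / 2 + rng.uniform(-jitter, jitter)
    cx = S / 2 + rng.uniform(-jitter, jitter)
    max_r = r0 * (1 + cfg.lobe_amplitude)
    if (cy - max_r < 0 or cx - max_r < 0 or cy + max_r > S or cx + max_r > S):
        import warnings

        warnings.warn("leaf radius exceeds image bounds; boundary clipped",
                      stacklevel=2)

    yy, xx = np.meshgrid(np.arange(S) + 0.5, np.arange(S) + 0.5, indexing="ij")
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = leaf_boundary_radius(theta, r0, cfg.n_lobes,
                                    cfg.lobe_amplitude, phase)
    mask = (rr <= boundary).astype(np.uint8)

    # leaf body: green texture + darker veins radiating from the centre
    h, s, v = _band_sample(rng, LEAF_HSV_BAND)
    vmap = np.clip(v + 0.10 * _smooth_noise(rng, S, 16) - 0.05, 0, 1)
    leaf = _hsv_to_rgb(np.full((S, S), h), np.full((S, S), s), vmap)
    vein_angle = rng.uniform(0, np.pi)
    for k in range(cfg.n_lobes + 2):
        ang = vein_angle + k * np.pi / (cfg.n_lobes + 2)
        dist = np.abs(dy * np.cos(ang) - dx * np.sin(ang))
        leaf = leaf * (1 - 0.25 * np.exp(-(dist / 1.5) ** 2))

    # disease spots: brown ellipses fully inside the leaf
    n_spots = rng.poisson(cfg.spot_density) if cfg.spot_density > 0 else 0
    for _ in range(n_spots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.6) * r0
        sy, sx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        a, b = rng.uniform(0.02, 0.06, 2) * S
        rot = rng.uniform(0, np.pi)
        u = (yy - sy) * np.cos(rot) + (xx - sx) * np.sin(rot)
        w = -(yy - sy) * np.sin(rot) + (xx - sx) * np.cos(rot)
        spot = ((u / a) ** 2 + (w / b) ** 2 <= 1) & (mask == 1)
        sh, ss, sv = _band_sample(rng, SPOT_HSV_BAND)
        color = _hsv_to_rgb(np.array([[sh]]), np.array([[ss]]),
                            np.array([[sv]]))[:, 0, 0]
        leaf = np.where(spot[None], color[:, None, None], leaf)

    image = _background(rng, S, cfg.background)
    image = np.where(mask[None] == 1, leaf, image)
    if cfg.illumination_gradient:
        gdir = rng.uniform(0, 2 * np.pi)
        ramp = (dy * np.sin(gdir) + dx * np.cos(gdir)) / S
        image = image * (1.0 + 0.25 * ramp)
    return np.clip(image, 0, 1).astype(np.float32), mask


def generate_dataset(n: int, cfg: LeafGenConfig, out_dir,
                     fractions=(0.733, 0.133, 0.134)) -> pd.DataFrame:
    """Write n image/mask PNG pairs plus a manifest CSV.

    Classes follow spot density: 0 -> healthy-leaf-like (HPL), otherwise the
    leaf alternates between the two diseased classes (SD/EBD).
    """
    from PIL import Image

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .data_io import split_dataset

    ids = [f"leaf_{i:04d}" for i in range(n)]
    split = split_dataset(ids, fractions=fractions, seed=cfg.seed) if n >= 3 else None
    rows = []
    for i, sample_id in enumerate(ids):
        sub = replace(cfg, seed=cfg.seed * 100003 + i)
        image, mask = generate_leaf(sub)
        img_path = out / f"{sample_id}.png"
        mask_path = out / f"{sample_id}_mask.png"
        Image.fromarray((image.transpose(1, 2, 0) * 255).astype(np.uint8)).save(
            img_path
        )
        save_mask(mask, mask_path)
        if cfg.spot_density == 0:
            cls = "HPL"
        else:
            cls = "SD" if i % 2 == 0 else "EBD"
        if split is None:
            part = "train"
        elif sample_id in split.train:
            part = "train"
        elif sample_id in split.val:
            part = "val"
        else:
            part = "test"
        rows.append(
            dict(id=sample_id, image_path=str(img_path),
                 mask_path=str(mask_path), split=part, **{"class": cls})
        )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
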