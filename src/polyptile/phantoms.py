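"""Synthetic colonoscopy-like phantom images with exact polyp masks.

Real colonoscopy frames show a pinkish, low-saturation bowel wall lit
unevenly by point sources, speckled with specular highlights, and -- where a
polyp protrudes -- a locally brighter, roughly hemispherical blob, possibly
with a shadowed base when seen from the side.  The phantom generator encodes
exactly these attributes and nothing more:

* background: narrow pink hue band, moderate saturation, a smooth
  illumination gradient across the frame plus large-scale soft mottling,
  broad darker wall folds, and thin darker vessel-like curves;
* polyps: additive hemispherical brightness profile
  ``I(r) = A * sqrt(max(0, R^2 - r^2)) / R`` with a slight desaturation, a
  darker contour ring at the circumference (the cue that makes a zenithal
  polyp outline distinguishable), plus a darker crescent at the base for
  lateral / semilateral views;
* specular reflections: small saturated white discs;
* sensor noise: i.i.d. Gaussian, clipped to [0, 1].

The binary mask is the exact union of the polyp disks, so tile labels
derived from it are noise-free ground truth.  Everything is driven by one
seed; a fixed seed reproduces the image bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .imaging import ColourSpace, ImageRecord

VIEWS = ("zenithal", "lateral", "semilateral")


@dataclass
class PhantomSpec:
    """Parameters of one phantom image.

    ``view='random'`` draws a view class per polyp.  Amplitudes are on the
    [0, 1] channel scale.
    """

    size: Tuple[int, int] = (200, 200)
    n_polyps: int = 1
    polyp_radius_range: Tuple[float, float] = (20.0, 40.0)
    view: str = "random"
    background_gradient: float = 0.15
    specular_count: int = 20
    noise_sigma: float = 0.01
    polyp_brightness: float = 0.35
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h <= 0 or w <= 0:
            raise ValueError("phantom size must be positive")
        rmin, rmax = self.polyp_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("invalid polyp radius range")
        if 2 * rmax > min(h, w):
            raise ValueError("polyp radii do not fit in the image")
        if self.view not in VIEWS + ("random",):
            raise ValueError(f"unknown view {self.view!r}")
        for amp in (self.background_gradient, self.noise_sigma,
                    self.polyp_brightness):
            if not 0 <= amp <= 1:
                raise ValueError("amplitudes must lie in [0, 1]")
        if self.n_polyps < 0 or self.specular_count < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class Polyp:
    center: Tuple[float, float]  # (row, col)
    radius: float
    view: str


@dataclass
class PhantomRecord:
    image: ImageRecord
    mask: np.ndarray
    ground_truth: List[Polyp] = field(default_factory=list)


def _place_polyps(spec: PhantomSpec, rng: np.random.Generator) -> List[Polyp]:
    h, w = spec.size
    rmin, rmax = spec.polyp_radius_range
    polyps: List[Polyp] = []
    for _ in range(spec.n_polyps):
        for attempt in range(100):
            radius = float(rng.uniform(rmin, rmax))
            margin = radius + 2
            if h - margin <= margin or w - margin <= margin:
                continue
            center = (float(rng.uniform(margin, h - margin)),
                      float(rng.uniform(margin, w - margin)))
            if all(np.hypot(center[0] - p.center[0], center[1] - p.center[1])
                   > 0.8 * (radius + p.radius) for p in polyps):
                break
        else:
            raise RuntimeError("could not place a polyp inside the frame")
        view = spec.view if spec.view != "random" \
            else VIEWS[int(rng.integers(len(VIEWS)))]
        polyps.append(Polyp(center=center, radius=radius, view=view))
    return polyps


def generate_phantom(spec: PhantomSpec) -> PhantomRecord:
    """Render one phantom image and its exact polyp mask."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    # bowel-wall background in HSV: narrow pink hue band, moderate
    # saturation, V with a smooth directional illumination gradient and a
    # large-scale sinusoidal mottling emulating the uneven wall
    # pink hue band kept clear of the 0/1 wrap point, since hue is handled
    # as a linear variable downstream
    hue = np.full((h, w), float(rng.uniform(0.93, 0.96)))
    sat = np.full((h, w), float(rng.uniform(0.25, 0.45)))
    val = np.full((h, w), 0.62)
    fr, fc = rng.uniform(1.0, 2.5, size=2)
    pr, pc = rng.uniform(0, 2 * np.pi, size=2)
    val = val + 0.03 * np.sin(2 * np.pi * fr * rows / h + pr) \
              * np.sin(2 * np.pi * fc * cols / w + pc)

    # bowel-wall folds: broad shallow shading arcs (large off-frame rings)
    for _ in range(int(rng.integers(2, 5))):
        fold_r = float(rng.uniform(0.8, 2.0)) * max(h, w)
        fold_th = float(rng.uniform(0, 2 * np.pi))
        fc0 = (h / 2 + fold_r * np.sin(fold_th),
               w / 2 + fold_r * np.cos(fold_th))
        ds = np.hypot(rows - fc0[0], cols - fc0[1])
        width = float(rng.uniform(8, 20))
        depth = float(rng.uniform(0.05, 0.12))
        val = val * (1.0 - depth * np.exp(-((ds - fold_r) / width) ** 2))

    # submucosal vessels: thin, slightly darker and more saturated curves
    vessels = np.zeros((h, w))
    for _ in range(int(rng.integers(3, 8))):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        for _step in range(int(rng.uniform(40, 120))):
            theta += rng.normal(0, 0.25)
            r0 += np.sin(theta)
            c0 += np.cos(theta)
            ir, ic = int(r0), int(c0)
            if 0 <= ir < h and 0 <= ic < w:
                vessels[ir, ic] = 1.0
    from scipy.ndimage import gaussian_filter
    vessels = gaussian_filter(vessels, 0.8)
    vessels /= max(vessels.max(), 1e-9)
    val = val - 0.10 * vessels
    sat = sat + 0.15 * vessels
    hue = hue - 0.015 * vessels

    polyps = _place_polyps(spec, rng)
    mask = np.zeros((h, w), dtype=np.uint8)
    for p in polyps:
        d = np.hypot(rows - p.center[0], cols - p.center[1])
        inside = d <= p.radius
        mask[inside] = 1
        # polyp tissue colour: slightly redder and less saturated than the
        # wall, uniformly over the protrusion (not just under the dome)
        hue = hue + 0.05 * inside
        sat = sat - 0.08 * inside
        # hemispherical (Lambertian-ish) brightness profile
        profile = np.sqrt(np.clip(p.radius ** 2 - d ** 2, 0, None)) / p.radius
        val = val + spec.polyp_brightness * profile
        sat = sat - 0.10 * profile  # protruding tissue looks lighter
        # circumference contour: a narrow dark ring at the disk rim makes
        # the polyp outline visible even where the dome shading vanishes
        rim = np.clip(1.0 - np.abs(d - p.radius) / 2.5, 0, None)
        val = val - 0.18 * rim
        sat = sat + 0.12 * rim
        if p.view in ("lateral", "semilateral"):
            # darker crescent at the base on one side of the blob
            depth = 0.25 if p.view == "lateral" else 0.15
            shadow_dir = rng.uniform(0, 2 * np.pi)
            off = (p.center[0] + 0.6 * p.radius * np.sin(shadow_dir),
                   p.center[1] + 0.6 * p.radius * np.cos(shadow_dir))
            ds = np.hypot(rows - off[0], cols - off[1])
            ring = np.clip(1.0 - np.abs(ds - p.radius) / (0.35 * p.radius),
                           0, None)
            val = val - depth * ring * (d > 0.6 * p.radius)

    # illumination: the scene is lit by near point sources, so the
    # reflectance image above is modulated by a smooth, strongly varying
    # field -- a directional ramp, an off-centre vignette and a per-image
    # exposure factor.  Smooth on the tile scale, so it rescales a tile's
    # intensities roughly multiplicatively.
    angle = float(rng.uniform(0, 2 * np.pi))
    ramp = (np.cos(angle) * cols / max(w - 1, 1)
            + np.sin(angle) * rows / max(h - 1, 1))
    cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
    r2 = ((rows - cy) ** 2 + (cols - cx) ** 2) / (max(h, w) ** 2)
    vignette = float(rng.uniform(0.2, 0.5))
    exposure = float(rng.uniform(0.8, 1.15))
    light = exposure * (1.0 + spec.background_gradient * (ramp - ramp.mean())) \
        * (1.0 - vignette * r2 / max(r2.max(), 1e-9))
    val = val * light

    # specular highlights: small saturated white discs
    for _ in range(spec.specular_count):
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        rad = rng.uniform(1.5, 7.0)
        d = np.hypot(rows - r0, cols - c0)
        spot = np.clip(1.0 - (d / rad) ** 2, 0, None)
        val = val + 0.9 * spot
        sat = sat - 0.9 * spot

    hsv = np.dstack([
        np.mod(hue, 1.0),
        np.clip(sat, 0.0, 1.0),
        np.clip(val, 0.0, 1.0),
    ])
    rgb = skcolor.hsv2rgb(hsv)
    rgb = rgb + rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    image = ImageRecord(pixels=rgb, mask=mask, colour_space=ColourSpace.RGB,
                        source_id=f"phantom-{spec.seed}")
    return PhantomRecord(image=image, mask=mask, ground_truth=polyps)


def generate_dataset(n_images: int, spec_template: PhantomSpec,
                     seed: int = 0) -> List[PhantomRecord]:
    """A reproducible collection of phantoms; per-image seeds derive from
    the master seed."""
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_images)
    records = []
    for i, s in enumerate(child_seeds):
        spec = replace(spec_template, seed=int(s))
        rec = generate_phantom(spec)
        rec.image.source_id = f"phantom-{seed}-{i:04d}"
        records.append(rec)
    return records


def write_dataset(records: Sequence[PhantomRecord], out_dir,
                  master_seed: Optional[int] = None) -> pd.DataFrame:
    """Write image/mask PNG pairs plus a manifest CSV; returns the manifest.

    The layout mirrors the public polyp-database convention (image plus
    same-size single-channel mask), so real data drops in unchanged.
    """
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        img_path = out / "images" / f"{rec.image.source_id}.png"
        mask_path = out / "masks" / f"{rec.image.source_id}.png"
        Image.fromarray(
            (rec.image.pixels * 255).round().astype(np.uint8)
        ).save(img_path)
        Image.fromarray((rec.mask * 255).astype(np.uint8)).save(mask_path)
        rows.append({
            "source_id": rec.image.source_id,
            "image_path": str(img_path),
            "mask_path": str(mask_path),
            "master_seed": master_seed,
            "n_polyps": len(rec.ground_truth),
            "polyps": ";".join(
                f"{p.center[0]:.1f},{p.center[1]:.1f},{p.radius:.1f},{p.view}"
                for p in rec.ground_truth),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
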