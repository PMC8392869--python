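"""Image and mask loading, colour-space conversion, tiling and tile labelling.

Colonoscopy frames arrive as 24-bit RGB rasters with an optional expert-drawn
binary mask marking polyp pixels on the same grid.  The classification unit of
the whole method is the square tile: images are partitioned into a
non-overlapping grid of ``tile_size`` x ``tile_size`` blocks, each tile is
labelled from the fraction of mask pixels it covers, and tiles are split into
training and test halves by strict index interleaving so the split is
deterministic and spatially balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor


class ColourSpace(str, Enum):
    RGB = "RGB"
    HSV = "HSV"


class TileLabel(str, Enum):
    POLYP = "polyp"
    NO_POLYP = "no_polyp"
    UNLABELED = "unlabeled"


@dataclass
class ImageRecord:
    """A colour image, its optional binary polyp mask, and provenance.

    ``pixels`` is an ``H x W x 3`` float array with every channel scaled to
    [0, 1] (hue is stored as angle/360 in HSV records).  ``mask`` shares the
    pixel grid; nonzero means polyp.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    colour_space: ColourSpace = ColourSpace.RGB
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("channel values must lie in [0, 1]")
        if self.mask is not None:
            self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"image grid {self.pixels.shape[:2]}"
                )
        self.colour_space = ColourSpace(self.colour_space)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class Tile:
    """A square pixel block cut from a source image.

    ``origin`` is the (row, col) of the top-left pixel, 0-based; the tile
    window is the half-open block [row, row+T) x [col, col+T).
    """

    pixels: np.ndarray
    origin: tuple
    source_id: str = ""
    mask_fraction: Optional[float] = None
    label: TileLabel = TileLabel.UNLABELED
    colour_space: ColourSpace = ColourSpace.RGB

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def load_image(path, mask_path=None, source_id: Optional[str] = None) -> ImageRecord:
    """Read a raster image (and optional mask) into an RGB :class:`ImageRecord`.

    8-bit channel values are scaled to [0, 1]; mask pixels are binarized
    (nonzero -> 1).  The mask must decode to the same H x W grid.
    """
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    mask = None
    if mask_path is not None:
        try:
            with Image.open(mask_path) as im:
                mask = np.asarray(im.convert("L"))
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read mask file {mask_path!r}: {exc}") from exc
        if mask.shape != rgb.shape[:2]:
            raise ValueError(
                f"mask dimensions {mask.shape} do not match image {rgb.shape[:2]}"
            )
    return ImageRecord(
        pixels=rgb,
        mask=mask,
        colour_space=ColourSpace.RGB,
        source_id=source_id if source_id is not None else str(path),
    )


def to_hsv(img: ImageRecord) -> ImageRecord:
    """Convert an RGB record to HSV with all channels on [0, 1].

    H and S suppress/highlight shadows better than raw RGB in endoscopic
    scenes, which is why the pipeline defaults to HSV features.  Hue is the
    angle divided by 360 degrees.
    """
    if img.colour_space is not ColourSpace.RGB:
        raise ValueError("to_hsv expects an RGB record")
    hsv = skcolor.rgb2hsv(img.pixels)
    return ImageRecord(
        pixels=hsv, mask=img.mask, colour_space=ColourSpace.HSV,
        source_id=img.source_id,
    )


def to_rgb(img: ImageRecord) -> ImageRecord:
    """Inverse of :func:`to_hsv`."""
    if img.colour_space is not ColourSpace.HSV:
        raise ValueError("to_rgb expects an HSV record")
    rgb = skcolor.hsv2rgb(img.pixels)
    return ImageRecord(
        pixels=np.clip(rgb, 0.0, 1.0), mask=img.mask,
        colour_space=ColourSpace.RGB, source_id=img.source_id,
    )


def tile_image(img: ImageRecord, tile_size: int) -> list:
    """Cut the image into non-overlapping full tiles in row-major order.

    Returns the floor(H/T) * floor(W/T) complete tiles; partial border
    remainders are discarded.  When the record carries a mask, each tile's
    ``mask_fraction`` is the fraction of its T*T pixels that are mask-positive.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    h, w = img.shape
    if tile_size > min(h, w):
        raise ValueError(
            f"tile_size {tile_size} exceeds image dimensions {h}x{w}"
        )
    t = int(tile_size)
    tiles = []
    for r in range(0, (h // t) * t, t):
        for c in range(0, (w // t) * t, t):
            frac = None
            if img.mask is not None:
                frac = float(img.mask[r:r + t, c:c + t].sum()) / (t * t)
            tiles.append(Tile(
                pixels=img.pixels[r:r + t, c:c + t].copy(),
                origin=(r, c),
                source_id=img.source_id,
                mask_fraction=frac,
                colour_space=img.colour_space,
            ))
    return tiles


def label_tiles(tiles: Sequence[Tile], polyp_fraction_threshold: float = 0.05) -> list:
    """Assign polyp / no_polyp labels from each tile's mask coverage.

    A tile is ``polyp`` when its mask_fraction reaches the threshold (or is
    strictly positive when the threshold is 0).  Returns new tiles; the input
    sequence is not modified.
    """
    if not 0.0 <= polyp_fraction_threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for tile in tiles:
        if tile.mask_fraction is None:
            raise ValueError(
                f"tile at {tile.origin} of {tile.source_id!r} has no mask_fraction"
            )
        if polyp_fraction_threshold > 0:
            is_polyp = tile.mask_fraction >= polyp_fraction_threshold
        else:
            is_polyp = tile.mask_fraction > 0
        out.append(replace(
            tile, label=TileLabel.POLYP if is_polyp else TileLabel.NO_POLYP
        ))
    return out


def split_train_test(tiles: Sequence[Tile]) -> tuple:
    """Deterministic even/odd interleaved split.

    Every second tile (indices 0, 2, 4, ...) of the row-major per-image order
    goes to training; the other half is the test set.  No randomness.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("cannot split an empty tile sequence")
    return tiles[0::2], tiles[1::2]


def tiles_to_frame(tiles: Sequence[Tile], tile_size: Optional[int] = None) -> pd.DataFrame:
    """Tabulate tile provenance and labels (CSV/TSV-ready)."""
    rows = []
    for t in tiles:
        rows.append({
            "source_id": t.source_id,
            "origin_row": t.origin[0],
            "origin_col": t.origin[1],
            "tile_size": t.size if tile_size is None else tile_size,
            "mask_fraction": t.mask_fraction,
            "label": t.label.value,
        })
    return pd.DataFrame(rows)
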