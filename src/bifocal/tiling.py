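"""Bifocal tile extraction, foreground detection and the whole-slide sweep
grid.

Every training or inference unit is a *bifocal pair*: a 512x512 context
(wide) tile and a 256x256 index (narrow) tile sharing one epicenter.  All
windows are half-open, ``[lo, hi)``.  The sweep grid enumerates epicenters
row-major from the upper-left to the bottom-right with a configurable
stride (default 50 px), admitting only fully in-bounds wide tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WIDE_SIZE",
    "NARROW_SIZE",
    "SlideImage",
    "BifocalPair",
    "TileGrid",
    "extract_bifocal_pair",
    "foreground_fraction",
    "tissue_mask",
    "is_foreground",
    "build_dataset",
    "enumerate_grid",
]

WIDE_SIZE = 512
NARROW_SIZE = 256

#: foreground (tissue vs. glass) rule, HSV: saturated or dark pixels are
#: tissue; a tile is foreground when at least this fraction of it is tissue.
SATURATION_THRESHOLD = 0.07
VALUE_THRESHOLD = 0.90
TILE_FOREGROUND_FRACTION = 0.25


@dataclass
class SlideImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    slide_id: str
    modality: str = "HE"

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise ValueError("slide must be an (H, W, 3) uint8 raster")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BifocalPair:
    wide: np.ndarray     # (512, 512, 3) uint8
    narrow: np.ndarray   # (256, 256, 3) uint8
    epicenter: tuple[int, int]
    label: str | None = None
    slide_id: str | None = None


@dataclass(frozen=True)
class TileGrid:
    """Sweep epicenters, row-major from upper-left to bottom-right.
    Cell (r, c) sits at pixel (origin + stride*c, origin + stride*r)."""

    rows: int
    cols: int
    stride: int
    origin: tuple[int, int] = (WIDE_SIZE // 2, WIDE_SIZE // 2)

    def center(self, r: int, c: int) -> tuple[int, int]:
        return (self.origin[0] + self.stride * c, self.origin[1] + self.stride * r)

    @property
    def centers(self) -> list[tuple[int, int]]:
        return [self.center(r, c) for r in range(self.rows) for c in range(self.cols)]

    def __len__(self) -> int:
        return self.rows * self.cols


def _crop_padded(img: np.ndarray, x0: int, y0: int, size: int, fill: int) -> np.ndarray:
    """Half-open window [x0, x0+size) x [y0, y0+size), out-of-bounds filled."""
    h, w = img.shape[:2]
    out = np.full((size, size, 3), fill, dtype=np.uint8)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + size, w), min(y0 + size, h)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    return out


def extract_bifocal_pair(
    slide: SlideImage,
    epicenter: tuple[int, int],
    pad_policy: str = "white",
    label: str | None = None,
) -> BifocalPair:
    """Extract the co-centered 512 (wide) and 256 (narrow) tiles at
    ``epicenter``; out-of-bounds pixels are filled per ``pad_policy``."""
    x, y = epicenter
    if not (0 <= x < slide.width and 0 <= y < slide.height):
        raise ValueError(
            f"epicenter ({x}, {y}) outside slide {slide.slide_id} "
            f"({slide.width}x{slide.height})"
        )
    if pad_policy not in ("white", "black"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    fill = 255 if pad_policy == "white" else 0
    wide = _crop_padded(slide.pixels, x - WIDE_SIZE // 2, y - WIDE_SIZE // 2, WIDE_SIZE, fill)
    narrow = _crop_padded(slide.pixels, x - NARROW_SIZE // 2, y - NARROW_SIZE // 2, NARROW_SIZE, fill)
    return BifocalPair(wide=wide, narrow=narrow, epicenter=(x, y), label=label, slide_id=slide.slide_id)


def tissue_mask(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel tissue test: saturation > 0.07 or value < 0.90 in HSV
    terms.  Glass (near-white, unsaturated) is background."""
    t = pixels.astype(np.float32) / 255.0
    mx = t.max(axis=2)
    mn = t.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-6), 0.0)
    return (sat > SATURATION_THRESHOLD) | (mx < VALUE_THRESHOLD)


def foreground_fraction(tile: np.ndarray) -> float:
    """Fraction of pixels deemed tissue (non-glass)."""
    return float(tissue_mask(tile).mean())


def is_foreground(tile: np.ndarray, threshold: float = TILE_FOREGROUND_FRACTION) -> bool:
    return foreground_fraction(tile) >= threshold


def build_dataset(slides, markings) -> list[BifocalPair]:
    """One labeled bifocal pair per marking dot.  ``slides`` is a list of
    SlideImage or a {slide_id: SlideImage} mapping."""
    if not isinstance(slides, dict):
        slides = {s.slide_id: s for s in slides}
    pairs: list[BifocalPair] = []
    for dot in markings:
        if dot.slide_id not in slides:
            raise ValueError(f"marking references unknown slide {dot.slide_id!r}")
        pairs.append(
            extract_bifocal_pair(slides[dot.slide_id], (dot.x, dot.y), label=dot.label)
        )
    return pairs


def enumerate_grid(slide_dims: tuple[int, int], stride: int = 50) -> TileGrid:
    """Sweep grid of fully in-bounds wide-tile centers.

    Per axis the center count is ``floor((dim - 512) / stride) + 1``; the
    first center sits at 256 (the first position where a full 512 tile fits)
    and subsequent centers advance by ``stride``.
    """
    w, h = slide_dims
    if w < WIDE_SIZE or h < WIDE_SIZE:
        raise ValueError(f"slide {w}x{h} smaller than one {WIDE_SIZE} tile")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    cols = (w - WIDE_SIZE) // stride + 1
    rows = (h - WIDE_SIZE) // stride + 1
    return TileGrid(rows=rows, cols=cols, stride=stride)
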