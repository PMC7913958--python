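"""Whole-slide sweep and heatmap assembly.

A sweep walks the stride grid (default 50 px) from the upper-left to the
bottom-right of a slide, extracts the bifocal pair at every center, and
classifies the foreground pairs — with no augmentation — into a
*probability heatmap*: one class-probability vector per grid cell, with
background (glass) cells flagged.  The argmax view of that grid is the
*classification heatmap* used for registration and fusion; the renderers
turn either into pseudo-color images, scaling each cell's color by its
winning probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tiling import (
    NARROW_SIZE,
    TILE_FOREGROUND_FRACTION,
    SlideImage,
    TileGrid,
    enumerate_grid,
    extract_bifocal_pair,
    tissue_mask,
)
from .training import downscale_tiles, normalize_batch

__all__ = [
    "ProbabilityHeatmap",
    "ClassificationHeatmap",
    "ModelClassifier",
    "TruthClassifier",
    "sweep_slide",
    "to_classification",
    "render_probability",
    "render_classification",
    "overlay",
    "default_palette",
    "save_heatmap",
    "load_heatmap",
    "BACKGROUND",
]

#: label value marking a background (glass) cell in classification heatmaps
BACKGROUND = -1

#: default pseudo-color palette: six distinct hues for the H&E feature
#: classes I..VI (also serves, truncated, for the 2-class IHC head where
#: index 0 = negative-blue, 1 = positive-brown via IHC_PALETTE).
HE_PALETTE = np.array(
    [
        (228, 26, 28),    # I   palisading necrosis - red
        (255, 255, 51),   # II  microvascular proliferation - yellow
        (77, 175, 74),    # III normal vessels - green
        (152, 78, 163),   # IV  geographic necrosis - purple
        (55, 126, 184),   # V   brain tissue - blue
        (255, 127, 0),    # VI  tumor background - orange
    ],
    dtype=np.uint8,
)
IHC_PALETTE = np.array([(70, 100, 200), (160, 90, 30)], dtype=np.uint8)  # negative, positive
BACKGROUND_COLOR = np.zeros(3, dtype=np.uint8)


def default_palette(n_classes: int) -> np.ndarray:
    if n_classes == 2:
        return IHC_PALETTE
    if n_classes <= len(HE_PALETTE):
        return HE_PALETTE[:n_classes]
    raise ValueError(f"no default palette for {n_classes} classes")


@dataclass
class ProbabilityHeatmap:
    probs: np.ndarray        # (rows, cols, n_classes) float32
    foreground: np.ndarray   # (rows, cols) bool
    stride: int
    origin: tuple[int, int]
    class_names: tuple[str, ...]

    @property
    def grid(self) -> TileGrid:
        return TileGrid(
            rows=self.probs.shape[0], cols=self.probs.shape[1], stride=self.stride, origin=self.origin
        )


@dataclass
class ClassificationHeatmap:
    labels: np.ndarray       # (rows, cols) int16; BACKGROUND marks glass
    stride: int
    origin: tuple[int, int]
    class_names: tuple[str, ...]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels != BACKGROUND


class ModelClassifier:
    """Adapts a trained network to the sweep: raw 512/256 uint8 tiles in,
    probability vectors out.  ``downscale`` must match the tile scale the
    network was trained at."""

    def __init__(self, model, downscale: int = 1):
        self.model = model
        self.downscale = downscale
        self.num_classes = model.config.num_classes

    def predict_proba(self, wide: np.ndarray, narrow: np.ndarray, centers) -> np.ndarray:
        w = downscale_tiles(wide, self.downscale)
        n = downscale_tiles(narrow, self.downscale)
        return self.model.predict_proba(normalize_batch(w), normalize_batch(n))


class TruthClassifier:
    """Ground-truth classifier stub: answers with a one-hot vector of the
    label field at the tile epicenter.  Lets the sweep/fusion stages be
    exercised deterministically, independent of training."""

    needs_tiles = False  # classifies from the label field, not pixels

    def __init__(self, field: np.ndarray, value_to_class: dict[int, int], num_classes: int):
        self.field = field
        self.value_to_class = value_to_class
        self.num_classes = num_classes

    @classmethod
    def for_he(cls, truth, n_classes: int = 6) -> "TruthClassifier":
        return cls(truth.he_classes, {v: v - 1 for v in range(1, n_classes + 1)}, n_classes)

    @classmethod
    def for_ihc(cls, truth) -> "TruthClassifier":
        # IHC head convention: class 0 = negative, 1 = positive
        return cls(truth.ihc_classes, {1: 0, 2: 1}, 2)

    def _cell_class(self, x: int, y: int) -> int:
        v = int(self.field[y, x])
        if v in self.value_to_class:
            return self.value_to_class[v]
        # epicenter on glass inside a foreground tile: majority vote nearby
        h, w = self.field.shape
        win = self.field[max(y - 32, 0) : y + 32, max(x - 32, 0) : x + 32]
        vals, counts = np.unique(win[win > 0], return_counts=True)
        if len(vals) == 0:
            return 0
        return self.value_to_class[int(vals[counts.argmax()])]

    def predict_proba(self, wide: np.ndarray, narrow: np.ndarray, centers) -> np.ndarray:
        out = np.zeros((len(centers), self.num_classes), dtype=np.float32)
        for i, (x, y) in enumerate(centers):
            out[i, self._cell_class(x, y)] = 1.0
        return out


def _foreground_grid(slide: SlideImage, grid: TileGrid, threshold: float) -> np.ndarray:
    """Per-cell foreground flags via an integral image of the tissue mask:
    identical to testing ``is_foreground`` on every narrow tile, but O(1)
    per cell."""
    mask = tissue_mask(slide.pixels)
    integ = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    integ[1:, 1:] = mask.cumsum(0).cumsum(1)
    half = NARROW_SIZE // 2
    out = np.zeros((grid.rows, grid.cols), dtype=bool)
    rr = np.arange(grid.rows)
    cc = np.arange(grid.cols)
    y0 = grid.origin[1] + grid.stride * rr - half
    x0 = grid.origin[0] + grid.stride * cc - half
    y1, x1 = y0 + NARROW_SIZE, x0 + NARROW_SIZE
    counts = (
        integ[np.ix_(y1, x1)] - integ[np.ix_(y0, x1)] - integ[np.ix_(y1, x0)] + integ[np.ix_(y0, x0)]
    )
    out[:] = counts >= threshold * NARROW_SIZE * NARROW_SIZE
    return out


def sweep_slide(
    classifier,
    slide: SlideImage,
    stride: int = 50,
    fg_threshold: float = TILE_FOREGROUND_FRACTION,
    batch_size: int = 64,
) -> ProbabilityHeatmap:
    """Classify every foreground grid pair of ``slide`` into a probability
    heatmap.  Background cells are never sent to the classifier."""
    grid = enumerate_grid((slide.width, slide.height), stride=stride)
    k = classifier.num_classes
    probs = np.zeros((grid.rows, grid.cols, k), dtype=np.float32)
    fg = _foreground_grid(slide, grid, fg_threshold)

    needs_tiles = getattr(classifier, "needs_tiles", True)
    cells = [(r, c) for r in range(grid.rows) for c in range(grid.cols) if fg[r, c]]
    for lo in range(0, len(cells), batch_size):
        chunk = cells[lo : lo + batch_size]
        centers = [grid.center(r, c) for r, c in chunk]
        if needs_tiles:
            pairs = [extract_bifocal_pair(slide, ctr) for ctr in centers]
            wide = np.stack([p.wide for p in pairs])
            narrow = np.stack([p.narrow for p in pairs])
        else:
            wide = narrow = np.empty((len(chunk), 0, 0, 3), dtype=np.uint8)
        p = classifier.predict_proba(wide, narrow, centers)
        if p.shape[1] != k:
            raise ValueError(f"classifier returned {p.shape[1]} classes, expected {k}")
        for (r, c), vec in zip(chunk, p):
            probs[r, c] = vec
    names = getattr(classifier, "class_names", tuple(str(i) for i in range(k)))
    return ProbabilityHeatmap(
        probs=probs, foreground=fg, stride=stride, origin=grid.origin, class_names=tuple(names)
    )


def to_classification(heatmap: ProbabilityHeatmap) -> ClassificationHeatmap:
    """Per-cell argmax; ties break toward the lowest class index."""
    labels = heatmap.probs.argmax(axis=2).astype(np.int16)
    labels[~heatmap.foreground] = BACKGROUND
    return ClassificationHeatmap(
        labels=labels, stride=heatmap.stride, origin=heatmap.origin, class_names=heatmap.class_names
    )


def render_probability(heatmap: ProbabilityHeatmap, palette: np.ndarray | None = None) -> np.ndarray:
    """Pseudo-color render: each foreground cell takes its argmax class
    color scaled linearly by that class's probability (1 -> full color,
    1/n_classes -> darkest); background cells take the background color."""
    k = heatmap.probs.shape[2]
    palette = default_palette(k) if palette is None else np.asarray(palette, dtype=np.uint8)
    if palette.shape[0] < k:
        raise ValueError(f"palette covers {palette.shape[0]} classes, need {k}")
    arg = heatmap.probs.argmax(axis=2)
    pmax = heatmap.probs.max(axis=2)
    weight = np.clip((pmax - 1.0 / k) / (1.0 - 1.0 / k), 0.0, 1.0)
    img = (palette[arg].astype(np.float32) * weight[:, :, None]).astype(np.uint8)
    img[~heatmap.foreground] = BACKGROUND_COLOR
    return img


def render_classification(heatmap: ClassificationHeatmap, palette: np.ndarray | None = None) -> np.ndarray:
    k = len(heatmap.class_names)
    palette = default_palette(k) if palette is None else np.asarray(palette, dtype=np.uint8)
    img = np.zeros((*heatmap.labels.shape, 3), dtype=np.uint8)
    fgm = heatmap.foreground
    img[fgm] = palette[heatmap.labels[fgm]]
    return img


def overlay(rendered: np.ndarray, slide: SlideImage, alpha: float) -> np.ndarray:
    """Transparent overlay: nearest-neighbour upsample of the heatmap render
    to slide size, then the per-pixel convex combination
    ``alpha * heatmap + (1 - alpha) * slide``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rows, cols = rendered.shape[:2]
    ys = np.clip(np.arange(slide.height) * rows // slide.height, 0, rows - 1)
    xs = np.clip(np.arange(slide.width) * cols // slide.width, 0, cols - 1)
    up = rendered[np.ix_(ys, xs)]
    out = alpha * up.astype(np.float32) + (1.0 - alpha) * slide.pixels.astype(np.float32)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def save_heatmap(heatmap: ProbabilityHeatmap | ClassificationHeatmap, path) -> None:
    """Persist a heatmap as a portable compressed array container."""
    common = dict(
        stride=heatmap.stride,
        origin=np.asarray(heatmap.origin),
        class_names=np.asarray(heatmap.class_names),
    )
    if isinstance(heatmap, ProbabilityHeatmap):
        np.savez_compressed(path, kind="probability", probs=heatmap.probs, foreground=heatmap.foreground, **common)
    else:
        np.savez_compressed(path, kind="classification", labels=heatmap.labels, **common)


def load_heatmap(path) -> ProbabilityHeatmap | ClassificationHeatmap:
    with np.load(path, allow_pickle=False) as d:
        kind = str(d["kind"])
        stride = int(d["stride"])
        origin = tuple(int(v) for v in d["origin"])
        names = tuple(str(s) for s in d["class_names"])
        if kind == "probability":
            return ProbabilityHeatmap(d["probs"], d["foreground"], stride, origin, names)
        return ClassificationHeatmap(d["labels"], stride, origin, names)
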