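"""Registration of the IHC classification heatmap onto the H&E heatmap,
fusion into a joint color map, and overlap quantification.

Adjacent sections differ by a near-rigid placement, so the transform family
is affine (2x3), estimated from point correspondences between the two
binarized (tissue vs. glass) heatmaps: centroids and boundary extrema of
connected foreground components, matched by area rank, give the initial
estimate under RANSAC; an optional iterative closest-point pass over the
component boundaries then refines it with many more correspondences.
Class labels are categorical, so warping resamples nearest-neighbour only.

Quantification follows the overlap statistics of the study: with Fhe(i) the
cell count of morphological feature i on the H&E heatmap and Ii the count
of those cells that are immunopositive after alignment, the positivity
share of feature i is ``Pi = Ii / Fhe(i)``.  Area percentages Phe/Pihc are
taken over foreground cells (glass area is meaningless as a denominator).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import estimate_transform as _sk_estimate

from .geometry import Affine
from .heatmap import BACKGROUND, ClassificationHeatmap, default_palette

__all__ = [
    "RegistrationError",
    "detect_correspondences",
    "estimate_transform",
    "register",
    "warp_heatmap",
    "FusionMap",
    "fuse",
    "default_color_table",
    "QuantReport",
    "quantify",
]

MAGENTA = (255, 0, 255)


class RegistrationError(RuntimeError):
    pass


def _component_points(mask: np.ndarray, min_area: int) -> list[tuple[float, np.ndarray]]:
    """Per connected component (area-descending): centroid plus the four
    boundary extrema, as (x, y) cell coordinates."""
    lab = measure.label(mask, connectivity=2)
    out = []
    for rp in measure.regionprops(lab):
        if rp.area < min_area:
            continue
        coords = rp.coords  # (row, col)
        cy, cx = rp.centroid
        top = coords[coords[:, 0].argmin()]
        bottom = coords[coords[:, 0].argmax()]
        left = coords[coords[:, 1].argmin()]
        right = coords[coords[:, 1].argmax()]
        pts = np.array(
            [
                (cx, cy),
                (top[1], top[0]),
                (bottom[1], bottom[0]),
                (left[1], left[0]),
                (right[1], right[0]),
            ],
            dtype=np.float64,
        )
        out.append((float(rp.area), pts))
    out.sort(key=lambda t: -t[0])
    return out


def detect_correspondences(
    he_map: ClassificationHeatmap,
    ihc_map: ClassificationHeatmap,
    min_area: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched point pairs (src in IHC cells, dst in H&E cells) derived from
    the foreground structure of the two heatmaps.

    Connected foreground components are matched across modalities by area
    rank (areas must agree within a factor of two); each matched component
    contributes its centroid and four boundary extrema.
    """
    he_comp = _component_points(he_map.foreground, min_area)
    ihc_comp = _component_points(ihc_map.foreground, min_area)
    if not he_comp or not ihc_comp:
        raise RegistrationError("a heatmap has no usable foreground component")
    src, dst = [], []
    for (a_ihc, pts_ihc), (a_he, pts_he) in zip(ihc_comp, he_comp):
        if max(a_ihc, a_he) > 2.0 * min(a_ihc, a_he):
            continue
        src.append(pts_ihc)
        dst.append(pts_he)
    if not src:
        raise RegistrationError("no component pair with comparable area found")
    src_pts = np.vstack(src)
    dst_pts = np.vstack(dst)
    if len(src_pts) < 3 or _collinear(src_pts):
        raise RegistrationError("fewer than 3 non-collinear correspondences")
    return src_pts, dst_pts


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 3:
        return True
    p = points - points.mean(axis=0)
    return np.linalg.matrix_rank(p, tol=max(tol, 1e-9 * np.abs(p).max())) < 2


def estimate_transform(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    seed: int = 0,
    residual_threshold: float = 1.0,
) -> Affine:
    """Least-squares affine from matched points with consensus (RANSAC)
    outlier rejection; falls back to a plain least-squares fit when the
    point set is too small to subsample."""
    src = np.asarray(src_points, dtype=np.float64)
    dst = np.asarray(dst_points, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) point arrays")
    if len(src) < 3:
        raise RegistrationError("need at least 3 point pairs")
    if _collinear(src) or _collinear(dst):
        raise RegistrationError("points are collinear; affine transform underdetermined")
    if len(src) > 3:
        model, inliers = measure.ransac(
            (src, dst),
            _SkAffine,
            min_samples=3,
            residual_threshold=residual_threshold,
            max_trials=1000,
            rng=seed,
        )
        if model is not None and inliers is not None and inliers.sum() >= 3:
            refit = _sk_estimate("affine", src[inliers], dst[inliers])
            return Affine(np.asarray(refit.params)[:2, :])
    fit = _sk_estimate("affine", src, dst)
    return Affine(np.asarray(fit.params)[:2, :])


def _boundary_points(mask: np.ndarray, frame_margin: int = 2) -> np.ndarray:
    """(x, y) centers of foreground cells with a background 4-neighbour.

    Cells within ``frame_margin`` of the grid frame are excluded: the sweep
    window clips tissue identically in both maps, and those straight cut
    edges would anchor the fit to the identity instead of the true motion.
    """
    pad = np.pad(mask, 1)
    interior = pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    edge = mask & ~interior
    if frame_margin > 0:
        edge = edge.copy()
        edge[:frame_margin, :] = False
        edge[-frame_margin:, :] = False
        edge[:, :frame_margin] = False
        edge[:, -frame_margin:] = False
    ys, xs = np.nonzero(edge)
    return np.column_stack([xs, ys]).astype(np.float64)


def register(
    he_map: ClassificationHeatmap,
    ihc_map: ClassificationHeatmap,
    seed: int = 0,
    points: tuple[np.ndarray, np.ndarray] | None = None,
    refine_iterations: int = 3,
) -> Affine:
    """Full registration: detected (or supplied) correspondences give an
    initial affine; iterative closest-point passes over the foreground
    boundaries refine it.  Returns the IHC-cells -> H&E-cells transform."""
    src, dst = points if points is not None else detect_correspondences(he_map, ihc_map)
    init = estimate_transform(src, dst, seed=seed)
    candidates = [Affine.identity()]
    if _plausible_section_transform(init):
        candidates.append(init)
    t = candidates[-1]
    if refine_iterations > 0:
        he_b = _boundary_points(he_map.foreground)
        ihc_b = _boundary_points(ihc_map.foreground)
        if len(he_b) >= 3 and len(ihc_b) >= 3:
            tree = cKDTree(he_b)
            for _ in range(refine_iterations):
                moved = t.apply(ihc_b)
                dist, idx = tree.query(moved)
                # trimmed ICP: refit on the best 80% of matches.  The refit
                # is a similarity (rotation + isotropic scale + shift), the
                # family adjacent-section placement actually lives in; the
                # extra affine degrees of freedom are underdetermined when
                # the tissue silhouette fills the sweep window.
                keep = np.argsort(dist)[: max(3, int(0.8 * len(dist)))]
                if _collinear(ihc_b[keep]):
                    break
                fit = _sk_estimate("similarity", ihc_b[keep], he_b[idx[keep]])
                new_t = Affine(np.asarray(fit.params)[:2, :])
                if not _plausible_section_transform(new_t):
                    break
                delta = new_t.max_abs_difference(t)
                t = new_t
                candidates.append(t)
                if delta < 1e-4:
                    break
    # model selection: the boundary signal can be weak when the tissue
    # silhouette fills the sweep window, so keep whichever candidate best
    # explains the foreground masks away from the window frame ...
    he_fg, ihc_fg = he_map.foreground, ihc_map.foreground
    scores = [_mask_agreement(he_fg, ihc_fg, c) for c in candidates]
    best = candidates[int(np.argmax(scores))]
    # ... and polish it by maximizing that agreement directly over the
    # similarity parameters (dense intensity-based refinement)
    polished = _refine_by_mask(he_fg, ihc_fg, best)
    if _plausible_section_transform(polished) and _mask_agreement(he_fg, ihc_fg, polished) >= max(scores):
        return polished
    return best


def _refine_by_mask(he_fg: np.ndarray, ihc_fg: np.ndarray, t0: Affine) -> Affine:
    """Nelder-Mead over (rotation, log-scale, shift) of a similarity applied
    on top of ``t0``, maximizing foreground-mask agreement."""
    from scipy.optimize import minimize

    center = ((he_fg.shape[1] - 1) / 2.0, (he_fg.shape[0] - 1) / 2.0)

    def build(params: np.ndarray) -> Affine:
        rot, log_s, tx, ty = params
        delta = Affine.from_params(
            rotation_deg=rot, scale=float(np.exp(log_s)), translation=(tx, ty), center=center
        )
        return delta.compose(t0)

    def neg_agreement(params: np.ndarray) -> float:
        return -_mask_agreement(he_fg, ihc_fg, build(params))

    # simplex steps sized to the problem (degrees, log-scale, cells): the
    # objective is piecewise constant, so steps must cross cell boundaries
    steps = np.array([1.0, 0.01, 1.5, 1.5])
    simplex = np.vstack([np.zeros(4)] + [steps[i] * np.eye(4)[i] for i in range(4)])
    res = minimize(
        neg_agreement,
        x0=np.zeros(4),
        method="Nelder-Mead",
        options={"maxiter": 250, "xatol": 1e-3, "fatol": 1e-7, "initial_simplex": simplex},
    )
    return build(res.x)


def _mask_agreement(he_fg: np.ndarray, ihc_fg: np.ndarray, t: Affine, frame: int = 3) -> float:
    """Fraction of interior H&E cells whose foreground flag matches the
    transformed IHC foreground flag."""
    rows, cols = he_fg.shape
    yy, xx = np.mgrid[frame : rows - frame, frame : cols - frame]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    src = t.inverse().apply(pts)
    sx = np.rint(src[:, 0]).astype(int)
    sy = np.rint(src[:, 1]).astype(int)
    ok = (sx >= 0) & (sx < ihc_fg.shape[1]) & (sy >= 0) & (sy < ihc_fg.shape[0])
    sampled = np.zeros(len(pts), dtype=bool)
    sampled[ok] = ihc_fg[sy[ok], sx[ok]]
    return float((sampled == he_fg[frame : rows - frame, frame : cols - frame].ravel()).mean())


def _plausible_section_transform(t: Affine, max_linear_dev: float = 0.15, max_shift_cells: float = 10.0) -> bool:
    """Adjacent sections sit nearly aligned: reject transforms far from the
    identity (they indicate a diverged fit, not real section placement)."""
    lin_dev = float(np.abs(t.linear - np.eye(2)).max())
    shift = float(np.abs(t.translation).max())
    return lin_dev <= max_linear_dev and shift <= max_shift_cells


def warp_heatmap(
    ihc_map: ClassificationHeatmap,
    transform: Affine,
    out_shape: tuple[int, int] | None = None,
) -> ClassificationHeatmap:
    """Resample the IHC classification heatmap onto the H&E grid by
    nearest-neighbour lookup through the inverse transform; cells that map
    outside the IHC grid become background."""
    rows, cols = out_shape if out_shape is not None else ihc_map.labels.shape
    inv = transform.inverse()
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    srcs = inv.apply(pts)
    sx = np.rint(srcs[:, 0]).astype(int)
    sy = np.rint(srcs[:, 1]).astype(int)
    h, w = ihc_map.labels.shape
    ok = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    out = np.full(rows * cols, BACKGROUND, dtype=np.int16)
    out[ok] = ihc_map.labels[sy[ok], sx[ok]]
    return ClassificationHeatmap(
        labels=out.reshape(rows, cols),
        stride=ihc_map.stride,
        origin=ihc_map.origin,
        class_names=ihc_map.class_names,
    )


# ---------------------------------------------------------------------------
# fusion


def default_color_table(n_he_classes: int = 6, positive_class: int = 1) -> dict:
    """Joint-state color table: one distinct RGB per (H&E state, IHC state).

    H&E states are class indices 0..n-1 plus BACKGROUND; IHC states are
    0 = negative, 1 = positive, BACKGROUND.  Magenta is reserved for the
    (microvascular proliferation, positive) pair.
    """
    he_palette = default_palette(n_he_classes).astype(np.int64)
    table: dict[tuple[int, int], tuple[int, int, int]] = {
        (BACKGROUND, BACKGROUND): (0, 0, 0),
        (BACKGROUND, 0): (40, 40, 40),
        (BACKGROUND, 1): (80, 50, 20),
    }
    for i in range(n_he_classes):
        base = he_palette[i]
        table[(i, BACKGROUND)] = tuple((base * 0.35).astype(int))
        table[(i, 0)] = tuple((base * 0.75).astype(int))
        table[(i, 1)] = tuple(np.clip(base * 0.55 + np.array([120, 0, 120]), 0, 255).astype(int))
    table[(positive_class, 1)] = MAGENTA
    if len(set(table.values())) != len(table):
        raise ValueError("color table entries are not distinct")
    return table


@dataclass
class FusionMap:
    """Joint H&E-class x IHC-state map on the H&E grid."""

    he_labels: np.ndarray
    ihc_labels: np.ndarray
    color_table: dict
    stride: int
    origin: tuple[int, int]
    class_names: tuple[str, ...]

    def render(self) -> np.ndarray:
        rows, cols = self.he_labels.shape
        img = np.zeros((rows, cols, 3), dtype=np.uint8)
        for (he_s, ihc_s), color in self.color_table.items():
            m = (self.he_labels == he_s) & (self.ihc_labels == ihc_s)
            img[m] = color
        return img


def fuse(
    he_map: ClassificationHeatmap,
    ihc_aligned: ClassificationHeatmap,
    color_table: dict | None = None,
) -> FusionMap:
    """Merge the H&E heatmap with the aligned IHC heatmap into a joint map;
    each color of the render encodes one (feature, immunostate) pair."""
    if he_map.labels.shape != ihc_aligned.labels.shape:
        raise ValueError(
            f"grid mismatch: {he_map.labels.shape} vs {ihc_aligned.labels.shape}"
        )
    n_he = len(he_map.class_names)
    table = color_table if color_table is not None else default_color_table(n_he)
    return FusionMap(
        he_labels=he_map.labels.copy(),
        ihc_labels=ihc_aligned.labels.copy(),
        color_table=table,
        stride=he_map.stride,
        origin=he_map.origin,
        class_names=he_map.class_names,
    )


# ---------------------------------------------------------------------------
# quantification


@dataclass
class QuantReport:
    """Per-class areas and overlap statistics.

    ``phe[i]``: percent of H&E foreground cells of class i (sums to 100).
    ``pihc``: percent of aligned-IHC foreground cells negative/positive.
    ``fhe[i]``: cell count of class i.  ``intersection[i]``: cells of class
    i that are immunopositive after alignment.  ``p[i]``: the positivity
    share intersection[i] / fhe[i], or None when fhe[i] = 0.
    """

    class_names: tuple[str, ...]
    phe: dict[int, float]
    pihc: dict[str, float]
    fhe: dict[int, int]
    intersection: dict[int, int]
    p: dict[int, float | None]

    def to_json(self, path=None) -> str:
        payload = {
            "class_names": list(self.class_names),
            "phe_percent": {self.class_names[i]: v for i, v in self.phe.items()},
            "pihc_percent": self.pihc,
            "fhe_cells": {self.class_names[i]: v for i, v in self.fhe.items()},
            "intersection_cells": {self.class_names[i]: v for i, v in self.intersection.items()},
            "positivity_share": {self.class_names[i]: v for i, v in self.p.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "class": self.class_names[i],
                "phe_percent": self.phe[i],
                "fhe_cells": self.fhe[i],
                "intersection_cells": self.intersection[i],
                "positivity_share": self.p[i],
            }
            for i in sorted(self.phe)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def quantify(
    he_map: ClassificationHeatmap,
    ihc_aligned: ClassificationHeatmap,
    positive_index: int = 1,
) -> QuantReport:
    """Overlap statistics between the H&E heatmap and the aligned IHC map.

    For each feature class i: Fhe(i) cells, the intersection Ii with the
    immunopositive area, and Pi = Ii / Fhe(i).  Classes absent from the
    heatmap get Pi = None (reported missing, never divided by zero).
    """
    if he_map.labels.shape != ihc_aligned.labels.shape:
        raise ValueError("heatmaps must share the same grid")
    n = len(he_map.class_names)
    he = he_map.labels
    ihc = ihc_aligned.labels
    he_fg = he != BACKGROUND
    ihc_fg = ihc != BACKGROUND
    n_he_fg = int(he_fg.sum())
    n_ihc_fg = int(ihc_fg.sum())
    phe, fhe, inter, p = {}, {}, {}, {}
    for i in range(n):
        m = he == i
        fhe[i] = int(m.sum())
        phe[i] = 100.0 * fhe[i] / n_he_fg if n_he_fg else 0.0
        inter[i] = int((m & (ihc == positive_index)).sum())
        if fhe[i] > 0:
            p[i] = inter[i] / fhe[i]
        else:
            warnings.warn(
                f"class {he_map.class_names[i]!r} absent from heatmap; share undefined",
                stacklevel=2,
            )
            p[i] = None
    pihc = {
        "positive": 100.0 * int((ihc == positive_index).sum()) / n_ihc_fg if n_ihc_fg else 0.0,
        "negative": 100.0 * int(((ihc != positive_index) & ihc_fg).sum()) / n_ihc_fg if n_ihc_fg else 0.0,
    }
    return QuantReport(
        class_names=he_map.class_names, phe=phe, pihc=pihc, fhe=fhe, intersection=inter, p=p
    )
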