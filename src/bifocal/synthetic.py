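"""Seeded generator of paired H&E-like / IHC-like slides with ground truth.

The generator emulates the statistical structure the pipeline assumes rather
than tissue appearance: a glass background, a tissue area partitioned into
contiguous regions of six texture classes (the morphological features
I-VI: palisading necrosis, microvascular proliferation, normal vessels,
geographic necrosis, brain tissue, tumor background), and a paired
"adjacent-section" IHC slide related to the H&E slide by a known small
affine transform, in which DAB-like brown positivity covers a prescribed
fraction of one chosen H&E class (the microvascular-proliferation analog).

Two classes — brain tissue (V) and tumor background (VI) — share the same
local base texture; class VI additionally carries sparse coarse "infiltrate"
discs whose spacing exceeds the narrow (256 px) tile but not the wide
(512 px) tile.  A narrow tile in class VI therefore sometimes looks exactly
like class V, while the wide tile almost always disambiguates: the context
path of the bifocal classifier is genuinely required on this pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .geometry import Affine
from .markings import CLASS_LABELS, IHC_LABELS, MarkingDot
from .tiling import SlideImage

__all__ = [
    "SyntheticSpec",
    "LabelField",
    "TextureParams",
    "generate_slide_pair",
    "sample_markings",
    "draw_section_transform",
    "DEFAULT_TEXTURES",
]

MIN_DIM = 1024  # at least one full 512 tile everywhere on the sweep grid
WIDE_MARGIN = 256  # half of a wide tile


@dataclass(frozen=True)
class TextureParams:
    """Per-class procedural texture: mean color plus low- and high-frequency
    luminance modulation (8-bit scale)."""

    base: tuple[float, float, float]
    amp_low: float = 10.0
    amp_white: float = 8.0


#: H&E-like palette; classes V and VI intentionally share the base texture.
DEFAULT_TEXTURES: dict[int, TextureParams] = {
    1: TextureParams((168, 96, 126), amp_low=16, amp_white=10),   # palisading necrosis
    2: TextureParams((146, 44, 84), amp_low=12, amp_white=10),    # microvascular proliferation
    3: TextureParams((226, 172, 190), amp_low=8, amp_white=8),    # normal vessels
    4: TextureParams((238, 206, 210), amp_low=6, amp_white=6),    # geographic necrosis
    5: TextureParams((208, 150, 162), amp_low=10, amp_white=8),   # brain tissue
    6: TextureParams((208, 150, 162), amp_low=10, amp_white=8),   # tumor background (+ discs)
}

#: coarse infiltrate discs distinguishing class VI from V
PATCH_COLOR = (60, 30, 80)
PATCH_RADIUS = 36
#: default jittered-grid disc spacing (px).  At 200 px nearly every narrow
#: tile of the disc-marked class sees a disc; widening the spacing to
#: ~284 px makes ~26% of narrow (256) tiles disc-free while ~98% of wide
#: (512) tiles still see one — that configuration makes the context path
#: genuinely necessary and drives the bifocal-vs-subnet comparison.
PATCH_SPACING = 200
RING_PATCH_SPACING = 284

#: IHC rendering
DAB_BROWN = (132, 82, 46)
COUNTERSTAIN_BLUE = (96, 108, 172)
GLASS = 245.0
#: share of the slide kept glass as interior holes (tears, vessel lumina)
HOLE_FRACTION = 0.12


@dataclass
class SyntheticSpec:
    width: int = 2048
    height: int = 2048
    n_classes: int = 6
    region_seed_count: int = 16
    texture_params: dict[int, TextureParams] = field(default_factory=lambda: dict(DEFAULT_TEXTURES))
    ihc_transform: Affine | None = None  # None -> drawn from the seed
    ihc_positive_class: int = 2
    positive_fraction_in_class: float = 0.75
    background_fraction: float = 0.30
    patch_spacing: int = PATCH_SPACING
    patch_jitter: float = 0.25  # disc-position jitter as a fraction of spacing
    rng_seed: int = 0

    def validate(self) -> None:
        if self.width < MIN_DIM or self.height < MIN_DIM:
            raise ValueError(
                f"slide dimensions must be >= {MIN_DIM} px so a 512 tile fits "
                f"everywhere on the grid; got {self.width}x{self.height}"
            )
        if not 0.0 <= self.positive_fraction_in_class <= 1.0:
            raise ValueError("positive_fraction_in_class must lie in [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if not 1 <= self.ihc_positive_class <= self.n_classes:
            raise ValueError("ihc_positive_class out of range")


@dataclass
class LabelField:
    """Ground truth for both modalities.

    ``he_classes``: per-pixel class map in the H&E frame (0 = glass,
    1..n = classes I..VI).  ``he_positive``: immunopositivity drawn in the
    H&E frame (subset of the positive class).  ``ihc_classes``: per-pixel
    map in the IHC frame (0 = glass, 1 = negative tissue, 2 = positive),
    i.e. the H&E-frame truth seen through the inter-section transform.
    """

    he_classes: np.ndarray
    he_positive: np.ndarray
    ihc_classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.he_classes.max())


def draw_section_transform(rng: np.random.Generator, center: tuple[float, float]) -> Affine:
    """Adjacent-section placement: rotation <= 3 deg, shift <= 40 px,
    isotropic scale in [0.98, 1.02], about the slide center."""
    rot = rng.uniform(-3.0, 3.0)
    scale = rng.uniform(0.98, 1.02)
    tx, ty = rng.uniform(-40.0, 40.0, size=2)
    return Affine.from_params(rotation_deg=rot, scale=scale, translation=(tx, ty), center=center)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field.  Large-sigma fields are
    synthesized on a coarse lattice and bilinearly upsampled, which is
    visually indistinguishable at slide scale and far cheaper."""
    ds = max(1, int(sigma / 8.0))
    hs, ws = max(shape[0] // ds, 8), max(shape[1] // ds, 8)
    f = ndimage.gaussian_filter(rng.normal(size=(hs, ws)).astype(np.float32), sigma / ds)
    if (hs, ws) != shape:
        f = resize(f, shape, order=1, anti_aliasing=False, preserve_range=True).astype(np.float32)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def interior_distance(field: np.ndarray) -> np.ndarray:
    """Distance (px) of every pixel to the nearest class boundary of a
    label field (glass counts as a class)."""
    boundary = np.zeros(field.shape, dtype=bool)
    diff_v = field[:-1, :] != field[1:, :]
    boundary[:-1, :] |= diff_v
    boundary[1:, :] |= diff_v
    diff_h = field[:, :-1] != field[:, 1:]
    boundary[:, :-1] |= diff_h
    boundary[:, 1:] |= diff_h
    return ndimage.distance_transform_edt(~boundary)


#: every class must keep an interior core so markings sample feature
#: interiors; clearance and border margin scale down on small slides


def core_clearance(h: int, w: int) -> int:
    return min(96, min(h, w) // 16)


def border_margin(h: int, w: int) -> int:
    return min(WIDE_MARGIN, min(h, w) // 8)


def _min_core_pixels(h: int, w: int, n_classes: int) -> int:
    m = border_margin(h, w)
    window = max(h - 2 * m, 1) * max(w - 2 * m, 1)
    return max(1500, window // (n_classes * 40))


def _partition(rng: np.random.Generator, spec: SyntheticSpec, tissue: np.ndarray) -> np.ndarray:
    """Wavy-boundary nearest-seed partition of the tissue into classes.
    Seeds are drawn from tissue pixels; the draw is repeated until every
    class retains a marking-sized interior core.  ``region_seed_count``
    refers to a 2048x2048 slide and scales with slide area, keeping region
    size (not region count) roughly constant."""
    h, w = tissue.shape
    n_seeds = max(spec.n_classes, round(spec.region_seed_count * (h * w) / 2048**2))
    if min(h, w) < 1536:
        # small slides need seed redundancy: with one region per class a
        # single unlucky placement starves that class of interior core
        n_seeds = max(n_seeds, 2 * spec.n_classes)
    min_core = _min_core_pixels(h, w, spec.n_classes)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    amp = min(h, w) / 32.0
    jx = amp * _smooth_field(rng, (h, w), sigma=min(h, w) / 16)
    jy = amp * _smooth_field(rng, (h, w), sigma=min(h, w) / 16)
    px, py = xx + jx, yy + jy
    tissue_flat = np.flatnonzero(tissue)
    margin = border_margin(h, w)
    clearance = core_clearance(h, w)
    glass_depth = ndimage.distance_transform_edt(tissue)
    for _ in range(20):  # re-draw seeds until every class keeps a core
        pick = rng.choice(tissue_flat, size=n_seeds, replace=False)
        seeds = np.column_stack(np.unravel_index(pick, tissue.shape))[:, ::-1]  # (x, y)
        cls_of_seed = np.array(
            [1 + i % spec.n_classes for i in range(n_seeds)], dtype=np.uint8
        )
        rng.shuffle(cls_of_seed)
        # the immunopositive class sits deep inside the tissue (vascular
        # proliferation away from section edges): swap its seeds with the
        # deepest ones so its regions rarely touch glass
        depth = glass_depth[seeds[:, 1].astype(int), seeds[:, 0].astype(int)]
        pos_c = spec.ihc_positive_class
        deepest = np.argsort(-depth)[: int((cls_of_seed == pos_c).sum())]
        rest = np.setdiff1d(np.arange(n_seeds), deepest)
        non_pos_labels = cls_of_seed[cls_of_seed != pos_c]
        cls_of_seed = np.empty(n_seeds, dtype=np.uint8)
        cls_of_seed[deepest] = pos_c
        cls_of_seed[rest] = non_pos_labels[: len(rest)]
        best = np.full((h, w), np.inf, dtype=np.float32)
        lab = np.zeros((h, w), dtype=np.uint8)
        for s, c in zip(seeds, cls_of_seed):
            d = (px - s[0]) ** 2 + (py - s[1]) ** 2
            closer = d < best
            best[closer] = d[closer]
            lab[closer] = c
        lab[~tissue] = 0
        # the immunopositive class must sit wholly inside the area covered
        # by sweep-grid cells (for strides up to 50 px): its regions carry
        # a designed interior/rim positivity structure that an uncovered
        # border band would truncate one-sidedly.  Pixels of that class in
        # the band are handed to the nearest other class.
        guard = margin + 80
        band = np.ones((h, w), dtype=bool)
        band[guard : h - guard, guard : w - guard] = False
        clipped = (lab == pos_c) & band
        if clipped.any():
            ys, xs = np.nonzero(clipped)
            best_d = np.full(len(ys), np.inf, dtype=np.float32)
            new_lab = np.zeros(len(ys), dtype=np.uint8)
            pxs, pys = px[ys, xs], py[ys, xs]
            for s_pt, c_cls in zip(seeds, cls_of_seed):
                if c_cls == pos_c:
                    continue
                d = (pxs - s_pt[0]) ** 2 + (pys - s_pt[1]) ** 2
                closer = d < best_d
                best_d[closer] = d[closer]
                new_lab[closer] = c_cls
            lab[ys, xs] = new_lab
        core = np.where(interior_distance(lab) >= clearance, lab, 0)
        core = core[margin : h - margin, margin : w - margin]
        counts = np.bincount(core.ravel(), minlength=spec.n_classes + 1)[1:]
        if (counts >= min_core).all():
            return lab
    raise RuntimeError("could not give every class an interior core; increase region_seed_count")


def _render_he(rng: np.random.Generator, spec: SyntheticSpec, classes: np.ndarray) -> np.ndarray:
    h, w = classes.shape
    low = _smooth_field(rng, (h, w), sigma=24.0)
    white = rng.normal(size=(h, w)).astype(np.float32)
    img = np.full((h, w, 3), GLASS, dtype=np.float32)
    img += rng.normal(scale=2.0, size=(h, w, 3)).astype(np.float32)
    for c in range(1, spec.n_classes + 1):
        tp = spec.texture_params[c]
        mask = classes == c
        mod = (tp.amp_low * low + tp.amp_white * white)[mask]
        img[mask] = np.asarray(tp.base, dtype=np.float32) + mod[:, None]
    # coarse infiltrate discs render only inside the last class (VI).
    # Jittered-grid placement keeps the local disc density uniform inside
    # every class-VI region (one candidate center per grid cell).
    ring_class = spec.n_classes
    s = spec.patch_spacing
    gy, gx = np.mgrid[0 : int(np.ceil(h / s)), 0 : int(np.ceil(w / s))]
    # disc position within its grid cell: centered, jittered by a fraction
    # of the spacing.  Small jitter bounds the largest disc-free gap (every
    # narrow tile of the class sees a disc); full jitter (1.0) makes disc
    # visibility in a narrow tile a coin toss — the ring-context regime.
    j = float(np.clip(spec.patch_jitter, 0.0, 1.0))
    jitter = s * ((1.0 - j) / 2.0 + j * rng.uniform(0, 1, size=(2,) + gx.shape))
    cxs = (gx * s + jitter[0]).ravel()
    cys = (gy * s + jitter[1]).ravel()
    inb = (cxs < w) & (cys < h)
    # every disc paints its intersection with the class region, so coverage
    # does not thin out near region boundaries
    centers = np.column_stack([cxs[inb], cys[inb]])
    r = PATCH_RADIUS
    for cx, cy in centers:
        x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
        y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        disc = ((xs - cx) ** 2 + (ys - cy) ** 2 <= r * r) & (classes[y0:y1, x0:x1] == ring_class)
        sub = img[y0:y1, x0:x1]
        sub[disc] = np.asarray(PATCH_COLOR, dtype=np.float32) + (
            8.0 * white[y0:y1, x0:x1][disc]
        )[:, None]
        img[y0:y1, x0:x1] = sub
    return np.clip(img, 0, 255).astype(np.uint8)


#: correlation length (px) and amplitude (px) of the wiggle added to the
#: interior-distance score that shapes the immunopositive core
POSITIVE_FIELD_SIGMA = 48.0
POSITIVE_WIGGLE_PX = 12.0


def _positive_mask(
    rng: np.random.Generator, spec: SyntheticSpec, classes: np.ndarray
) -> np.ndarray:
    """Spatially coherent positivity covering the prescribed fraction of the
    chosen class, enforced separately in every connected region.

    Positivity forms the *interior core* of each region: the score is the
    distance to the region border plus a smooth wiggle, thresholded at the
    top-f quantile.  A rim of the region therefore stays negative, which
    matches immunopositivity concentrating inside its morphological feature
    and keeps the designed overlap fraction insensitive to the small
    residual misalignments of heatmap-level registration.
    """
    mask = classes == spec.ihc_positive_class
    f = spec.positive_fraction_in_class
    pos = np.zeros_like(mask)
    if mask.sum() == 0 or f == 0.0:
        return pos
    if f >= 1.0:
        pos[mask] = True
        return pos
    field = _smooth_field(rng, classes.shape, sigma=POSITIVE_FIELD_SIGMA)
    comp, n_comp = ndimage.label(mask)
    objects = ndimage.find_objects(comp)
    for c, sl in zip(range(1, n_comp + 1), objects):
        sly = slice(max(sl[0].start - 1, 0), sl[0].stop + 1)
        slx = slice(max(sl[1].start - 1, 0), sl[1].stop + 1)
        m = comp[sly, slx] == c
        # distance to the *outer* region border: interior glass holes are
        # filled first, so the negative rim follows the region outline and
        # hole rims keep the region's average positivity
        d = ndimage.distance_transform_edt(ndimage.binary_fill_holes(m))
        score = (d + POSITIVE_WIGGLE_PX * field[sly, slx])[m]
        n = score.size
        k = int(round(f * n))
        if k == 0:
            continue
        if k >= n:
            pos[sly, slx][m] = True
            continue
        kth = np.partition(score, n - k)[n - k]
        sub = pos[sly, slx]
        sub[m] = score >= kth  # continuous score: ties are measure-zero
        pos[sly, slx] = sub
    return pos


def _warp_labels(arr: np.ndarray, transform: Affine, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour sampling: out[q] = arr[transform(q)], 0 outside."""
    h, w = out_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    a, t = transform.linear, transform.translation
    sx = a[0, 0] * xx + a[0, 1] * yy + t[0]
    sy = a[1, 0] * xx + a[1, 1] * yy + t[1]
    return ndimage.map_coordinates(arr, [sy, sx], order=0, mode="constant", cval=0)


def _render_ihc(rng: np.random.Generator, ihc_classes: np.ndarray) -> np.ndarray:
    h, w = ihc_classes.shape
    img = np.full((h, w, 3), GLASS, dtype=np.float32)
    img += rng.normal(scale=2.0, size=(h, w, 3)).astype(np.float32)
    white = rng.normal(size=(h, w)).astype(np.float32)
    for value, color, amp in ((1, COUNTERSTAIN_BLUE, 9.0), (2, DAB_BROWN, 9.0)):
        mask = ihc_classes == value
        img[mask] = np.asarray(color, dtype=np.float32) + (amp * white[mask])[:, None]
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_slide_pair(
    spec: SyntheticSpec,
) -> tuple[SlideImage, SlideImage, LabelField, Affine]:
    """Generate an H&E-like slide, its adjacent-section IHC-like slide, the
    ground-truth label fields and the true inter-section transform.

    All outputs are pure functions of ``spec`` (including ``rng_seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width

    base_field = _smooth_field(rng, (h, w), sigma=min(h, w) / 10)
    # repel tissue from the slide border, as a mounted section sits inside
    # its glass margins; this also keeps every region fully visible to the
    # sweep grid (whose centers stay >= 256 px from the border)
    taper = min(320, min(h, w) // 8)
    yy = np.minimum(np.arange(h), np.arange(h)[::-1]).astype(np.float32)
    xx = np.minimum(np.arange(w), np.arange(w)[::-1]).astype(np.float32)
    border = np.minimum(yy[:, None], xx[None, :])
    tissue_field = base_field - 3.0 * (1.0 - np.clip(border / taper, 0.0, 1.0)) ** 2
    thr = np.quantile(tissue_field, spec.background_fraction)
    tissue = tissue_field >= thr
    # interior glass holes (tears, large vessel lumina): a coarser field's
    # lowest dips stay glass wherever they fall.  The holes are wider than
    # a narrow tile, so they survive the tile-level foreground test and
    # give every slide silhouette structure inside the sweep window — the
    # structure registration anchors to
    hole_field = _smooth_field(rng, (h, w), sigma=min(h, w) / 5)
    tissue &= hole_field >= np.quantile(hole_field, HOLE_FRACTION)

    classes = _partition(rng, spec, tissue)
    he_img = _render_he(rng, spec, classes)
    positive = _positive_mask(rng, spec, classes)

    transform = (
        spec.ihc_transform
        if spec.ihc_transform is not None
        else draw_section_transform(rng, center=(w / 2.0, h / 2.0))
    )
    cls_w = _warp_labels(classes, transform, (h, w))
    pos_w = _warp_labels(positive.astype(np.uint8), transform, (h, w))
    ihc_classes = np.zeros((h, w), dtype=np.uint8)
    ihc_classes[cls_w > 0] = 1
    ihc_classes[(cls_w > 0) & (pos_w > 0)] = 2
    ihc_img = _render_ihc(rng, ihc_classes)

    truth = LabelField(he_classes=classes, he_positive=positive, ihc_classes=ihc_classes)
    he = SlideImage(pixels=he_img, slide_id="synthetic_he", modality="HE")
    ihc = SlideImage(pixels=ihc_img, slide_id="synthetic_ihc", modality="IHC")
    return he, ihc, truth, transform


def sample_markings(
    truth: LabelField | np.ndarray,
    dots_per_class: int,
    margin: int | None = None,
    rng_seed: int = 0,
    modality: str = "HE",
    slide_id: str = "synthetic",
    boundary_clearance: int | None = None,
) -> list[MarkingDot]:
    """Draw ``dots_per_class`` expert-marking coordinates per class, each
    inside its class region, at least ``margin`` px from the slide border
    and at least ``boundary_clearance`` px from any class boundary — an
    expert marks the interior of a feature, not its rim.

    For H&E the classes are the region labels I..VI; for IHC they are
    positive/negative tissue.  Deterministic given ``rng_seed``.
    """
    if isinstance(truth, LabelField):
        field_arr = truth.he_classes if modality == "HE" else truth.ihc_classes
    else:
        field_arr = truth
    h, w = field_arr.shape
    if margin is None:
        margin = border_margin(h, w)
    if boundary_clearance is None:
        boundary_clearance = core_clearance(h, w)
    if margin * 2 >= min(h, w):
        raise ValueError("margin leaves no interior to sample from")
    if boundary_clearance > 0:
        dist = interior_distance(field_arr)
        field_arr = np.where(dist >= boundary_clearance, field_arr, 0)
    interior = field_arr[margin : h - margin, margin : w - margin]
    rng = np.random.default_rng(rng_seed)
    if modality == "HE":
        labels = {c + 1: CLASS_LABELS[c] for c in range(int(field_arr.max()))}
    else:
        labels = {1: "negative", 2: "positive"}
        assert set(labels.values()) <= set(IHC_LABELS)
    dots: list[MarkingDot] = []
    for value, name in labels.items():
        flat = np.flatnonzero(interior == value)
        if flat.size < dots_per_class:
            raise ValueError(
                f"class {name!r} has only {flat.size} pixels at margin {margin}; "
                f"cannot draw {dots_per_class} markings"
            )
        chosen = rng.choice(flat, size=dots_per_class, replace=False)
        ys, xs = np.unravel_index(chosen, interior.shape)
        for x, y in zip(xs, ys):
            dots.append(
                MarkingDot(
                    slide_id=slide_id,
                    x=int(x) + margin,
                    y=int(y) + margin,
                    label=name,
                    modality=modality,
                )
            )
    return dots
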