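"""Bifocal extraction, foreground rule and sweep-grid arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bifocal.markings import MarkingDot
from bifocal.tiling import (
    NARROW_SIZE,
    WIDE_SIZE,
    SlideImage,
    build_dataset,
    enumerate_grid,
    extract_bifocal_pair,
    foreground_fraction,
    tissue_mask,
)


def _slide(pixels, sid="s0"):
    return SlideImage(pixels=pixels, slide_id=sid)


def _gray(h=1024, w=1024, value=128):
    return np.full((h, w, 3), value, dtype=np.uint8)


def test_center_extraction_of_uniform_slide():
    pair = extract_bifocal_pair(_slide(_gray()), (512, 512))
    assert pair.wide.shape == (512, 512, 3)
    assert pair.narrow.shape == (256, 256, 3)
    assert (pair.wide == 128).all() and (pair.narrow == 128).all()


def test_narrow_is_central_crop_of_wide(rng):
    img = rng.integers(0, 255, size=(1024, 1024, 3), dtype=np.uint8)
    pair = extract_bifocal_pair(_slide(img), (400, 700))
    np.testing.assert_array_equal(pair.narrow, pair.wide[128:384, 128:384])


def test_corner_extraction_pads_white_against_manual_oracle(rng):
    img = rng.integers(0, 255, size=(1024, 1024, 3), dtype=np.uint8)
    pair = extract_bifocal_pair(_slide(img), (0, 0), pad_policy="white")
    # manual oracle: only the bottom-right quadrant holds slide content
    oracle = np.full((512, 512, 3), 255, dtype=np.uint8)
    oracle[256:, 256:] = img[:256, :256]
    np.testing.assert_array_equal(pair.wide, oracle)
    oracle_n = np.full((256, 256, 3), 255, dtype=np.uint8)
    oracle_n[128:, 128:] = img[:128, :128]
    np.testing.assert_array_equal(pair.narrow, oracle_n)


def test_epicenter_outside_slide_rejected():
    with pytest.raises(ValueError, match="outside"):
        extract_bifocal_pair(_slide(_gray()), (2000, 10))


def test_foreground_fraction_extremes_and_half():
    assert foreground_fraction(np.full((64, 64, 3), 255, np.uint8)) == 0.0
    saturated = np.zeros((64, 64, 3), np.uint8)
    saturated[..., 0] = 255
    assert foreground_fraction(saturated) == 1.0
    half = np.full((64, 64, 3), 255, np.uint8)
    half[:, :32, 0] = 200
    half[:, :32, 1] = 60
    half[:, :32, 2] = 60
    assert foreground_fraction(half) == pytest.approx(0.5, abs=0.01)


def test_tissue_mask_consistent_with_fraction(rng):
    tile = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
    assert foreground_fraction(tile) == tissue_mask(tile).mean()


def test_build_dataset_one_pair_per_dot_with_matching_histogram(rng):
    img = rng.integers(0, 255, size=(1024, 1024, 3), dtype=np.uint8)
    slides = [_slide(img, "a"), _slide(img, "b")]
    labels = ["I", "II", "III", "IV", "V", "VI"] * 10
    dots = [
        MarkingDot(["a", "b"][i % 2], int(rng.integers(1024)), int(rng.integers(1024)), lab, "HE")
        for i, lab in enumerate(labels)
    ]
    pairs = build_dataset(slides, dots)
    assert len(pairs) == len(dots)
    from collections import Counter

    assert Counter(p.label for p in pairs) == Counter(labels)


def test_build_dataset_missing_slide_names_it(rng):
    dots = [MarkingDot("ghost", 5, 5, "I", "HE")]
    with pytest.raises(ValueError, match="ghost"):
        build_dataset([_slide(_gray(), "a")], dots)


@pytest.mark.parametrize(
    "dims,stride,expected",
    [
        ((2048, 2048), 50, (31, 31)),
        ((512, 512), 50, (1, 1)),
        ((561, 512), 50, (1, 1)),
        ((562, 512), 50, (2, 1)),
    ],
)
def test_grid_counts_match_closed_form(dims, stride, expected):
    grid = enumerate_grid(dims, stride)
    assert (grid.cols, grid.rows) == expected
    if dims == (512, 512):
        assert grid.centers == [(256, 256)]


def test_grid_rejects_undersized_slides():
    with pytest.raises(ValueError):
        enumerate_grid((511, 2048), 50)


@given(
    w=st.integers(min_value=512, max_value=3000),
    h=st.integers(min_value=512, max_value=3000),
    stride=st.integers(min_value=1, max_value=600),
)
def test_grid_matches_exhaustive_enumeration(w, h, stride):
    """Oracle: enumerate every center x = 256 + k*stride whose wide tile
    fits fully in bounds."""
    grid = enumerate_grid((w, h), stride)
    half = WIDE_SIZE // 2
    xs = [x for x in range(half, w, stride) if x - half >= 0 and x + half <= w]
    ys = [y for y in range(half, h, stride) if y + half <= h]
    assert grid.cols == len(xs)
    assert grid.rows == len(ys)
    assert [grid.center(0, i) for i in range(min(3, len(xs)))] == [
        (xs[i], ys[0]) for i in range(min(3, len(xs)))
    ]


def test_grid_cell_center_roundtrip():
    grid = enumerate_grid((2048, 2048), 50)
    assert grid.center(0, 0) == (256, 256)
    assert grid.center(3, 7) == (256 + 50 * 7, 256 + 50 * 3)


def test_slide_image_validation():
    with pytest.raises(ValueError):
        SlideImage(pixels=np.zeros((10, 10), dtype=np.uint8), slide_id="x")
    with pytest.raises(ValueError):
        SlideImage(pixels=np.zeros((10, 10, 3), dtype=np.float32), slide_id="x")
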