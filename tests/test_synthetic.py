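"""Generator contracts: determinism, partition structure, designed
immunopositive overlap, marking placement."""

import dataclasses

import numpy as np
import pytest

from bifocal.synthetic import (
    LabelField,
    SyntheticSpec,
    generate_slide_pair,
    sample_markings,
)
from bifocal.markings import CLASS_LABELS


def test_fixed_seed_yields_byte_identical_outputs(small_spec, small_slide_pair):
    he2, ihc2, truth2, t2 = generate_slide_pair(dataclasses.replace(small_spec))
    assert np.array_equal(small_slide_pair["he"].pixels, he2.pixels)
    assert np.array_equal(small_slide_pair["ihc"].pixels, ihc2.pixels)
    assert np.array_equal(small_slide_pair["truth"].he_classes, truth2.he_classes)
    np.testing.assert_array_equal(small_slide_pair["transform"].matrix, t2.matrix)


def test_different_seed_changes_the_slide(small_spec, small_slide_pair):
    he2, *_ = generate_slide_pair(dataclasses.replace(small_spec, rng_seed=99))
    assert not np.array_equal(small_slide_pair["he"].pixels, he2.pixels)


def test_partition_covers_tissue_with_exactly_one_class(small_slide_pair):
    truth = small_slide_pair["truth"]
    classes = truth.he_classes
    assert classes.min() >= 0 and classes.max() == 6
    present = np.unique(classes)
    assert set(present) == set(range(7))  # glass + all six features
    # positivity is confined to the designated class
    assert not np.any(truth.he_positive & (classes != 2))


def test_designed_positive_fraction_recovered_by_pixel_count(small_slide_pair):
    """Brute-force pixel counting on the returned truth recovers the
    prescribed 0.75 within the binomial tolerance."""
    truth = small_slide_pair["truth"]
    mask = truth.he_classes == 2
    frac = truth.he_positive[mask].mean()
    assert frac == pytest.approx(0.75, abs=0.02)


@pytest.mark.parametrize("f,expected", [(0.0, 0.0), (1.0, 1.0)])
def test_positive_fraction_extremes(small_spec, f, expected):
    spec = dataclasses.replace(small_spec, positive_fraction_in_class=f, width=1024, height=1024)
    _, _, truth, _ = generate_slide_pair(spec)
    mask = truth.he_classes == 2
    assert truth.he_positive[mask].mean() == expected


def test_ihc_truth_equals_he_truth_through_the_transform(small_slide_pair):
    """Sampling the H&E-frame truth through the true transform reproduces
    the IHC-frame truth (same nearest-neighbour rule the renderer used)."""
    truth = small_slide_pair["truth"]
    t = small_slide_pair["transform"]
    h, w = truth.ihc_classes.shape
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.integers(0, w, 500), rng.integers(0, h, 500)])
    src = t.apply(pts)
    sx, sy = np.rint(src[:, 0]).astype(int), np.rint(src[:, 1]).astype(int)
    ok = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    cls = np.zeros(len(pts), dtype=int)
    cls[ok] = truth.he_classes[sy[ok], sx[ok]]
    pos = np.zeros(len(pts), dtype=bool)
    pos[ok] = truth.he_positive[sy[ok], sx[ok]]
    expected = np.where(cls == 0, 0, np.where(pos, 2, 1))
    got = truth.ihc_classes[pts[:, 1], pts[:, 0]]
    assert (expected == got).mean() > 0.99  # rint-vs-floor edges only


def test_too_small_slide_is_rejected():
    with pytest.raises(ValueError, match="512"):
        SyntheticSpec(width=800, height=2048).validate()
    with pytest.raises(ValueError):
        SyntheticSpec(positive_fraction_in_class=1.5).validate()


def test_markings_land_inside_their_class(small_slide_pair):
    truth = small_slide_pair["truth"]
    dots = sample_markings(truth, dots_per_class=10, rng_seed=3)
    assert len(dots) == 60
    for d in dots:
        assert truth.he_classes[d.y, d.x] == CLASS_LABELS.index(d.label) + 1


def test_marking_determinism_and_seed_sensitivity(small_slide_pair):
    truth = small_slide_pair["truth"]
    a = sample_markings(truth, 10, rng_seed=3)
    b = sample_markings(truth, 10, rng_seed=3)
    c = sample_markings(truth, 10, rng_seed=4)
    assert a == b
    coords = lambda dots: {(d.x, d.y) for d in dots}
    assert len(coords(a) & coords(c)) < 5  # disjoint with high probability


def test_ihc_markings_use_positive_negative_labels(small_slide_pair):
    truth = small_slide_pair["truth"]
    dots = sample_markings(truth, 8, rng_seed=5, modality="IHC")
    assert {d.label for d in dots} == {"positive", "negative"}
    for d in dots:
        expect = 2 if d.label == "positive" else 1
        assert truth.ihc_classes[d.y, d.x] == expect


def test_absent_class_raises_naming_the_class(small_slide_pair):
    field = np.where(small_slide_pair["truth"].he_classes == 6, 0, small_slide_pair["truth"].he_classes)
    # class VI still reported as the largest label by max(); removing a
    # mid-range class triggers the shortage error for it
    field = np.where(field == 3, 0, field)
    with pytest.raises(ValueError, match="'III'"):
        sample_markings(
            LabelField(he_classes=field, he_positive=np.zeros_like(field, bool), ihc_classes=field),
            dots_per_class=10,
            rng_seed=0,
        )


def test_requesting_more_dots_than_core_pixels_fails(small_slide_pair):
    with pytest.raises(ValueError, match="cannot draw"):
        sample_markings(small_slide_pair["truth"], dots_per_class=10**6, rng_seed=0)
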