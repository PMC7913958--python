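"""Whole-slide sweep, heatmap structure, rendering and overlay."""

import numpy as np
import pytest

from bifocal import augment
from bifocal.heatmap import (
    BACKGROUND,
    ClassificationHeatmap,
    ProbabilityHeatmap,
    TruthClassifier,
    default_palette,
    load_heatmap,
    overlay,
    render_probability,
    save_heatmap,
    sweep_slide,
    to_classification,
)
from bifocal.tiling import SlideImage, enumerate_grid


def _prob_heatmap(probs, fg=None, names=None):
    probs = np.asarray(probs, dtype=np.float32)
    fg = np.ones(probs.shape[:2], bool) if fg is None else fg
    names = tuple(str(i) for i in range(probs.shape[2])) if names is None else names
    return ProbabilityHeatmap(probs=probs, foreground=fg, stride=50, origin=(256, 256), class_names=names)


class CountingClassifier:
    """Records how many tiles it was asked to classify."""

    def __init__(self, num_classes=6):
        self.num_classes = num_classes
        self.calls = 0

    def predict_proba(self, wide, narrow, centers):
        self.calls += len(centers)
        out = np.zeros((len(centers), self.num_classes), np.float32)
        out[:, 0] = 1.0
        return out


def test_sweep_grid_matches_enumerate_grid(small_slide_pair):
    he = small_slide_pair["he"]
    truth = small_slide_pair["truth"]
    heat = sweep_slide(TruthClassifier.for_he(truth), he, stride=50)
    grid = enumerate_grid((he.width, he.height), 50)
    assert heat.probs.shape == (grid.rows, grid.cols, 6)
    assert heat.foreground.any()
    # foreground cells carry unit-sum vectors; background cells are null
    fg = heat.foreground
    assert np.abs(heat.probs[fg].sum(axis=1) - 1).max() < 1e-6
    assert np.all(heat.probs[~fg] == 0)


def test_truth_sweep_agrees_with_label_field_at_centers(small_slide_pair):
    he = small_slide_pair["he"]
    truth = small_slide_pair["truth"]
    heat = sweep_slide(TruthClassifier.for_he(truth), he, stride=50)
    cls = to_classification(heat)
    grid = heat.grid
    agree, total = 0, 0
    for r in range(grid.rows):
        for c in range(grid.cols):
            if cls.labels[r, c] == BACKGROUND:
                continue
            x, y = grid.center(r, c)
            t = truth.he_classes[y, x]
            if t > 0:
                total += 1
                agree += int(cls.labels[r, c] == t - 1)
    assert total > 50
    assert agree / total >= 0.99


def test_blank_slide_never_calls_the_classifier():
    blank = SlideImage(np.full((1024, 1024, 3), 250, np.uint8), "blank")
    clf = CountingClassifier()
    heat = sweep_slide(clf, blank, stride=100)
    assert clf.calls == 0
    assert not heat.foreground.any()


def test_sweep_is_batch_size_independent_and_never_augments(small_slide_pair):
    he = small_slide_pair["he"]
    truth = small_slide_pair["truth"]
    before = augment.call_count()
    h1 = sweep_slide(TruthClassifier.for_he(truth), he, stride=100, batch_size=7)
    h2 = sweep_slide(TruthClassifier.for_he(truth), he, stride=100, batch_size=64)
    np.testing.assert_array_equal(h1.probs, h2.probs)
    assert augment.call_count() == before  # recognition stage is augmentation-free


def test_to_classification_argmax_and_tie_break():
    hm = _prob_heatmap(
        [[[0.1, 0.7, 0.2], [1 / 3, 1 / 3, 1 / 3]]],
    )
    cls = to_classification(hm)
    assert cls.labels[0, 0] == 1
    assert cls.labels[0, 1] == 0  # uniform tie falls to the lowest index


def test_to_classification_marks_background():
    hm = _prob_heatmap([[[1.0, 0.0], [0.5, 0.5]]], fg=np.array([[True, False]]))
    cls = to_classification(hm)
    assert cls.labels[0, 1] == BACKGROUND
    assert cls.foreground.tolist() == [[True, False]]


def test_render_full_probability_gives_exact_palette_color():
    pal = default_palette(6)
    vec = np.zeros(6)
    vec[2] = 1.0
    hm = _prob_heatmap([[vec]])
    img = render_probability(hm)
    np.testing.assert_array_equal(img[0, 0], pal[2])


def test_render_background_color_and_brightness_monotonicity():
    v9 = np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
    v5 = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
    hm = _prob_heatmap([[v9, v5]], fg=np.array([[True, True]]))
    img = render_probability(hm)
    assert img[0, 0].astype(int).sum() > img[0, 1].astype(int).sum()
    hm_bg = _prob_heatmap([[v9]], fg=np.array([[False]]))
    np.testing.assert_array_equal(render_probability(hm_bg)[0, 0], (0, 0, 0))


def test_render_rejects_short_palette():
    hm = _prob_heatmap([[np.full(6, 1 / 6)]])
    with pytest.raises(ValueError, match="palette"):
        render_probability(hm, palette=np.zeros((3, 3), np.uint8))


def test_overlay_alpha_extremes_and_mean(rng):
    slide = SlideImage(rng.integers(0, 255, (128, 128, 3), dtype=np.uint8), "s")
    rendered = rng.integers(0, 255, (4, 4, 3), dtype=np.uint8)
    assert np.array_equal(overlay(rendered, slide, 0.0), slide.pixels)
    up = overlay(rendered, slide, 1.0)
    assert set(map(tuple, up.reshape(-1, 3))) <= set(map(tuple, rendered.reshape(-1, 3)))
    mid = overlay(rendered, slide, 0.5)
    expect = np.rint(0.5 * up[3, 3].astype(float) + 0.5 * slide.pixels[3, 3]).astype(np.uint8)
    np.testing.assert_array_equal(mid[3, 3], expect)
    with pytest.raises(ValueError):
        overlay(rendered, slide, 1.5)


def test_heatmap_container_roundtrip(tmp_path):
    hm = _prob_heatmap(np.random.default_rng(0).random((3, 4, 6)))
    save_heatmap(hm, tmp_path / "p.npz")
    back = load_heatmap(tmp_path / "p.npz")
    assert isinstance(back, ProbabilityHeatmap)
    np.testing.assert_array_equal(back.probs, hm.probs)
    assert back.stride == 50 and back.origin == (256, 256)
    cls = to_classification(hm)
    save_heatmap(cls, tmp_path / "c.npz")
    back_c = load_heatmap(tmp_path / "c.npz")
    assert isinstance(back_c, ClassificationHeatmap)
    np.testing.assert_array_equal(back_c.labels, cls.labels)
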