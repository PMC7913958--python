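"""Registration, categorical warping, fusion colors and overlap statistics."""

import numpy as np
import pytest

from bifocal.geometry import Affine
from bifocal.heatmap import BACKGROUND, ClassificationHeatmap
from bifocal.fusion import (
    MAGENTA,
    RegistrationError,
    default_color_table,
    detect_correspondences,
    estimate_transform,
    fuse,
    quantify,
    warp_heatmap,
)

HE6 = ("I", "II", "III", "IV", "V", "VI")


def _cls(labels, names=HE6, stride=50):
    return ClassificationHeatmap(
        labels=np.asarray(labels, dtype=np.int16), stride=stride, origin=(256, 256), class_names=names
    )


def _blob_map(rng, shape=(40, 40), n_blobs=3, n_classes=6):
    lab = np.full(shape, BACKGROUND, np.int16)
    for i in range(n_blobs):
        cy, cx = rng.integers(8, shape[0] - 8), rng.integers(8, shape[1] - 8)
        r = rng.integers(3, 6 + i)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = rng.integers(0, n_classes)
    return _cls(lab)


# --- transform estimation -------------------------------------------------


def test_identity_points_give_identity_transform(rng):
    pts = rng.uniform(0, 50, (8, 2))
    t = estimate_transform(pts, pts)
    assert t.max_abs_difference(Affine.identity()) < 1e-9


def test_known_affine_recovered_exactly(rng):
    true = Affine.from_params(rotation_deg=2.0, scale=1.01, translation=(5, 7), center=(25, 25))
    src = rng.uniform(0, 60, (10, 2))
    t = estimate_transform(src, true.apply(src))
    assert t.max_abs_difference(true) < 1e-6


def test_gross_outliers_rejected_by_consensus(rng):
    true = Affine.from_params(rotation_deg=-2.5, scale=0.99, translation=(-8, 4), center=(30, 30))
    src = rng.uniform(0, 60, (10, 2))
    dst = true.apply(src)
    dst[2] += (40, -33)
    dst[7] += (-28, 51)
    t = estimate_transform(src, dst, seed=0)
    assert t.max_abs_difference(true) < 1e-3


def test_collinear_points_rejected():
    src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    with pytest.raises(RegistrationError, match="collinear"):
        estimate_transform(src, src + 1)
    with pytest.raises(RegistrationError, match="3"):
        estimate_transform(src[:2], src[:2])


# --- correspondences ------------------------------------------------------


def test_identical_maps_match_with_zero_displacement(rng):
    m = _blob_map(rng)
    src, dst = detect_correspondences(m, m)
    assert len(src) >= 3
    np.testing.assert_allclose(src, dst)


def test_translated_map_detected_with_known_shift(rng):
    m = _blob_map(rng)
    shifted = np.full_like(m.labels, BACKGROUND)
    shifted[3:, 2:] = m.labels[:-3, :-2]
    src, dst = detect_correspondences(m, _cls(shifted))
    disp = dst - src
    med = np.median(disp, axis=0)
    assert med[0] == pytest.approx(-2, abs=0.5)
    assert med[1] == pytest.approx(-3, abs=0.5)


def test_blank_map_fails_registration(rng):
    blank = _cls(np.full((40, 40), BACKGROUND, np.int16))
    with pytest.raises(RegistrationError):
        detect_correspondences(_blob_map(rng), blank)


# --- warping --------------------------------------------------------------


def test_identity_warp_preserves_labels(rng):
    m = _blob_map(rng)
    out = warp_heatmap(m, Affine.identity())
    np.testing.assert_array_equal(out.labels, m.labels)


def test_integer_translation_shifts_labels_exactly(rng):
    m = _blob_map(rng)
    t = Affine(np.array([[1.0, 0, 4.0], [0, 1.0, 2.0]]))  # ihc -> he shift
    out = warp_heatmap(m, t)
    # oracle: index shift with background backfill
    oracle = np.full_like(m.labels, BACKGROUND)
    oracle[2:, 4:] = m.labels[:-2, :-4]
    np.testing.assert_array_equal(out.labels, oracle)


def test_warp_inverse_warp_mostly_restores_interior(rng):
    m = _blob_map(rng, shape=(60, 60), n_blobs=4)
    t = Affine.from_params(rotation_deg=2.5, scale=1.01, translation=(1.3, -0.8), center=(30, 30))
    there = warp_heatmap(m, t)
    back = warp_heatmap(there, t.inverse())
    inner = np.s_[5:-5, 5:-5]
    agree = (back.labels[inner] == m.labels[inner]).mean()
    assert agree >= 0.95


def test_non_invertible_transform_rejected():
    with pytest.raises(ValueError, match="singular"):
        Affine(np.array([[1.0, 2.0, 0.0], [0.5, 1.0, 0.0]]))


# --- fusion ---------------------------------------------------------------


def test_mvp_positive_cell_is_magenta():
    he = _cls([[1]])
    ihc = _cls([[1]], names=("negative", "positive"))
    fm = fuse(he, ihc)
    np.testing.assert_array_equal(fm.render()[0, 0], MAGENTA)


def test_background_background_is_black():
    he = _cls([[BACKGROUND]])
    ihc = _cls([[BACKGROUND]], names=("negative", "positive"))
    np.testing.assert_array_equal(fuse(he, ihc).render()[0, 0], (0, 0, 0))


def test_all_joint_states_render_distinct_colors():
    table = default_color_table(6)
    assert len(table) == 21  # (6 classes + background) x (neg, pos, background)
    assert len(set(table.values())) == 21
    he_states = [BACKGROUND] + list(range(6))
    ihc_states = [BACKGROUND, 0, 1]
    rendered = set()
    for hs in he_states:
        for is_ in ihc_states:
            fm = fuse(_cls([[hs]]), _cls([[is_]], names=("negative", "positive")))
            rendered.add(tuple(fm.render()[0, 0]))
    assert len(rendered) == 21


def test_fusion_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        fuse(_cls(np.zeros((3, 3))), _cls(np.zeros((4, 3)), names=("negative", "positive")))


# --- quantification -------------------------------------------------------


def _quant_oracle(he, ihc, n_classes, positive=1):
    he_fg = he != BACKGROUND
    fhe = {i: int((he == i).sum()) for i in range(n_classes)}
    inter = {i: int(((he == i) & (ihc == positive)).sum()) for i in range(n_classes)}
    phe = {i: 100.0 * fhe[i] / he_fg.sum() for i in range(n_classes)}
    p = {i: (inter[i] / fhe[i] if fhe[i] else None) for i in range(n_classes)}
    return fhe, inter, phe, p


def test_full_and_zero_overlap():
    he = _cls(np.full((4, 4), 1))
    pos = _cls(np.ones((4, 4)), names=("negative", "positive"))
    neg = _cls(np.zeros((4, 4)), names=("negative", "positive"))
    assert quantify(he, pos).p[1] == 1.0
    assert quantify(he, neg).p[1] == 0.0


def test_toy_grid_three_quarters():
    he = np.full((4, 4), BACKGROUND, np.int16)
    he[0, :4] = 1  # four cells of the vascular class
    ihc = np.full((4, 4), BACKGROUND, np.int16)
    ihc[0, :3] = 1  # three of them positive
    ihc[0, 3] = 0
    with pytest.warns(UserWarning):
        rep = quantify(_cls(he), _cls(ihc, names=("negative", "positive")))
    assert rep.fhe[1] == 4
    assert rep.intersection[1] == 3
    assert rep.p[1] == 0.75


def test_quantify_matches_bruteforce_on_random_grids(rng):
    """Cell-count oracle over 100 random grids; Pi is the exact ratio of
    integer counts."""
    for _ in range(100):
        shape = (rng.integers(3, 12), rng.integers(3, 12))
        he = rng.integers(-1, 6, size=shape).astype(np.int16)
        ihc = rng.integers(-1, 2, size=shape).astype(np.int16)
        if not (he != BACKGROUND).any() or not (ihc != BACKGROUND).any():
            continue
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rep = quantify(_cls(he), _cls(ihc, names=("negative", "positive")))
        fhe, inter, phe, p = _quant_oracle(he, ihc, 6)
        assert rep.fhe == fhe and rep.intersection == inter
        for i in range(6):
            assert rep.phe[i] == pytest.approx(phe[i])
            if fhe[i]:
                assert rep.p[i] == inter[i] / fhe[i]  # bit-exact integer ratio
            else:
                assert rep.p[i] is None
        # conservation: class areas partition the foreground
        assert sum(rep.fhe.values()) == int((he != BACKGROUND).sum())
        assert sum(rep.phe.values()) == pytest.approx(100.0, abs=1e-9)


def test_quantify_reports_ihc_percentages():
    he = _cls(np.zeros((2, 2), np.int16))
    ihc = _cls(np.array([[1, 0], [0, BACKGROUND]]), names=("negative", "positive"))
    with pytest.warns(UserWarning):
        rep = quantify(he, ihc)
    assert rep.pihc["positive"] == pytest.approx(100 / 3)
    assert rep.pihc["negative"] == pytest.approx(200 / 3)
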