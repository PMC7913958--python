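"""Desk-scale benchmarks: seeded synthetic tasks sized to run on one CPU.

These reproduce, at reduced scale, the study regimes the pipeline targets:

* ``recognition_benchmark`` — six-class recognition from bifocal pairs
  extracted at expert markings on 2048x2048 synthetic slides, trained and
  tested on different slides (case-level split).
* ``bifocal_comparison`` — the context-sensitive two-class task (brain
  tissue vs. tumor background) on which the narrow tile alone is sometimes
  ambiguous; trains the bifocal net and its single-path subnet with matched
  budgets and seeds.
* ``fusion_recovery`` — the end-to-end registration + fusion +
  quantification loop on a generated slide pair with a known inter-section
  transform and a known immunopositive fraction of the microvascular-
  proliferation analog class.

The benchmark model presents tiles block-mean downsampled 8x (64/32 inputs)
at base width 8: the texture classes live at color/coarse-structure scale,
so the reduced resolution preserves the task while keeping a training run
in the minutes range.  The parameter-budget claim is always checked on the
full-width default configuration, which downsampling does not affect.
"""

from __future__ import annotations

import dataclasses

from .fusion import quantify, register, warp_heatmap
from .heatmap import TruthClassifier, sweep_slide, to_classification
from .markings import CLASS_LABELS
from .metrics import EvalReport, roc_auc_ovr
from .model import BCNNConfig, build_bcnn, build_subnet
from .synthetic import (
    DEFAULT_TEXTURES,
    RING_PATCH_SPACING,
    SyntheticSpec,
    generate_slide_pair,
    sample_markings,
)
from .tiling import build_dataset
from .training import PairDataset, TrainConfig, evaluate, predict_batch, train

__all__ = [
    "BENCH_DOWNSCALE",
    "bench_model_config",
    "make_marked_slides",
    "recognition_benchmark",
    "bifocal_comparison",
    "fusion_recovery",
]

BENCH_DOWNSCALE = 8  # tiles fed at 64 (wide) / 32 (narrow)


def bench_model_config(num_classes: int = 6, rng_seed: int = 0) -> BCNNConfig:
    return BCNNConfig(
        num_classes=num_classes,
        base_width=8,
        blocks_per_stage=(1, 1, 1, 1),
        input_sizes=(512 // BENCH_DOWNSCALE, 256 // BENCH_DOWNSCALE),
        rng_seed=rng_seed,
    )


def make_marked_slides(
    seed: int,
    n_slides: int,
    dots_per_class: int,
    size: int = 2048,
    keep_labels: tuple[str, ...] | None = None,
    spec_overrides: dict | None = None,
):
    """Generate ``n_slides`` H&E slides with markings; returns (slides,
    markings, truths)."""
    slides, dots, truths = [], [], []
    for k in range(n_slides):
        spec = SyntheticSpec(
            width=size, height=size, rng_seed=seed * 1000 + k, **(spec_overrides or {})
        )
        he, _ihc, truth, _t = generate_slide_pair(spec)
        he = dataclasses.replace(he, slide_id=f"slide_{seed}_{k}")
        d = sample_markings(truth, dots_per_class, rng_seed=seed * 1000 + k, slide_id=he.slide_id)
        if keep_labels is not None:
            d = [m for m in d if m.label in keep_labels]
        slides.append(he)
        dots.extend(d)
        truths.append(truth)
    return slides, dots, truths


def _dataset(slides, dots, class_names) -> PairDataset:
    pairs = build_dataset(slides, dots)
    return PairDataset.from_pairs(pairs, class_names, downscale=BENCH_DOWNSCALE)


def recognition_benchmark(
    seed: int = 0,
    n_train_slides: int = 2,
    dots_train: int = 75,
    dots_test: int = 60,
    epochs: int = 8,
) -> EvalReport:
    """Six-class held-out evaluation of the bifocal net on synthetic slides.
    Train and test tiles come from different slides."""
    train_slides, train_dots, _ = make_marked_slides(seed, n_train_slides, dots_train)
    test_slides, test_dots, _ = make_marked_slides(seed + 500, 1, dots_test)
    ds_train = _dataset(train_slides, train_dots, CLASS_LABELS)
    ds_test = _dataset(test_slides, test_dots, CLASS_LABELS)
    model = build_bcnn(bench_model_config(6, rng_seed=seed))
    cfg = TrainConfig(epochs=epochs, rng_seed=seed)
    model, history = train(model, ds_train, cfg)
    return evaluate(model, ds_test, history=history)


#: the ring-context task: both classes carry the brain-tissue base texture;
#: the second additionally shows coarse infiltrate discs, whose spacing
#: exceeds the narrow tile's reach.  Few large regions keep each region much
#: bigger than a wide tile, so disc visibility in a narrow tile is a coin
#: the classifier cannot load.
_RING_TASK = dict(
    n_classes=2,
    region_seed_count=6,
    texture_params={1: DEFAULT_TEXTURES[5], 2: DEFAULT_TEXTURES[6]},
    ihc_positive_class=1,
    patch_spacing=RING_PATCH_SPACING,
    patch_jitter=1.0,
)


def bifocal_comparison(
    seed: int = 0,
    dots_train: int = 110,
    dots_test: int = 60,
    epochs: int = 5,
) -> tuple[float, float]:
    """Macro AUC of the bifocal net vs. its narrow-only subnet on the
    context-sensitive brain-tissue / tumor-background pair, with matched
    data, budgets and seeds.  Returns (auc_bifocal, auc_subnet)."""
    keep = ("I", "II")  # task-local names for (plain, disc-marked) texture
    train_slides, train_dots, _ = make_marked_slides(
        seed + 100, 1, dots_train, spec_overrides=_RING_TASK
    )
    test_slides, test_dots, _ = make_marked_slides(
        seed + 600, 1, dots_test, spec_overrides=_RING_TASK
    )
    ds_train = _dataset(train_slides, train_dots, keep)
    ds_test = _dataset(test_slides, test_dots, keep)
    cfg = TrainConfig(epochs=epochs, rng_seed=seed)
    results = []
    for build in (build_bcnn, build_subnet):
        model = build(bench_model_config(2, rng_seed=seed))
        model, _ = train(model, ds_train, dataclasses.replace(cfg))
        probs = predict_batch(model, ds_test.wide, ds_test.narrow)
        _, macro = roc_auc_ovr(ds_test.labels, probs, list(keep))
        results.append(macro)
    return results[0], results[1]


def fusion_recovery(
    seed: int = 0,
    positive_fraction: float = 0.75,
    size: int = 2560,
    stride: int = 25,
) -> dict:
    """End-to-end recovery of the designed immunopositive overlap.

    Generates a slide pair with a known inter-section transform, sweeps both
    slides with the ground-truth classifier stub (the deterministic
    pipeline variant), registers the IHC classification heatmap onto the
    H&E one from detected correspondences, fuses and quantifies.  Returns
    the quantification report fields plus registration diagnostics.
    """
    # region_seed_count is area-scaled by the generator; 10 here yields ~16
    # regions at the 2560 px benchmark size, keeping every feature region
    # several times larger than a wide tile
    spec = SyntheticSpec(
        width=size,
        height=size,
        positive_fraction_in_class=positive_fraction,
        region_seed_count=10,
        rng_seed=seed,
    )
    he, ihc, truth, true_t = generate_slide_pair(spec)

    he_clf = TruthClassifier.for_he(truth, n_classes=spec.n_classes)
    ihc_clf = TruthClassifier.for_ihc(truth)
    he_heat = sweep_slide(he_clf, he, stride=stride)
    ihc_heat = sweep_slide(ihc_clf, ihc, stride=stride)
    he_map = to_classification(he_heat)
    ihc_map = to_classification(ihc_heat)

    est_t = register(he_map, ihc_map, seed=seed)
    aligned = warp_heatmap(ihc_map, est_t, out_shape=(he_map.labels.shape))
    report = quantify(he_map, aligned, positive_index=1)

    true_cell = true_t.to_cell_frame(he_heat.origin, he_heat.stride)
    return {
        "p_ii": report.p[1],
        "report": report,
        "true_fraction": positive_fraction,
        "transform_error_cells": est_t.max_abs_difference(true_cell),
        "estimated_transform": est_t,
        "true_transform_cells": true_cell,
    }
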