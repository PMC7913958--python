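# Methods

## Overview

`bifocal` implements a complete desk-scale analogue of a bifocal
whole-slide analysis pipeline for glioblastoma histology: expert marking
dots on H&E and IHC slides define training tiles; a two-path convolutional
classifier learns six morphological feature classes (palisading necrosis I,
microvascular proliferation II, normal vessels III, geographic necrosis IV,
brain tissue V, tumor background VI) on H&E and positive/negative DAB
immunoreactivity on IHC; a stride-50 sliding sweep turns a trained
classifier into per-cell probability and classification heatmaps; and a
registration + fusion stage aligns the IHC heatmap of an adjacent section
onto the H&E heatmap and quantifies the spatial overlap of immunopositivity
with each morphological feature.

## The bifocal classifier

Each training or inference unit is a *bifocal pair*: a 512×512 context
(wide) tile and a concentric 256×256 index (narrow) tile, both half-open
windows `[lo, hi)` around a shared epicenter. Two structurally identical
convolutional subnets — a 7×7 stride-2 stem followed by four stages of
bottleneck-style triple convolutions (1×1 → 3×3 → 1×1×4), batch
normalization after every convolution, **no identity shortcuts** — process
the two tiles independently. Global average pooling makes the two feature
vectors equal-length regardless of the differing input sizes; they are
concatenated and classified by a single fully connected softmax layer.

The subnets do not share weights; with the default block counts
(2, 2, 2, 2) each path carries 26 weighted layers including the shared
classifier. The default width (base 32, doubling per stage, bottleneck
expansion 4) was chosen so the six-class network's 5 613 382 trainable
parameters stay at 23.9 % of the canonical 50-layer residual reference with
a six-class head (23 520 326; the same enumeration reproduces the
literature figure 25 557 032 for the 1000-class head). The parameter budget
— at most half of the reference — is enforced at construction: violating
configurations are flagged and warned about.

Because no GPU tensor framework is assumed, the layers are implemented
directly in NumPy (im2col convolution on BLAS, explicit backward passes,
Adam). The backward passes are verified against central-difference
gradients to ~1e-7 in float64.

## Training

Cross-entropy with inverse-frequency class weights, Adam at 1e-3, batch 32,
early stopping on validation loss (patience 5) with restoration of the best
epoch's weights *and* batch-norm running statistics. Validation splits and
cross-validation folds are case-level: whole slides, never tiles, are held
out. Augmentation draws one perturbation independently per pair member —
right-angle rotation, contrast or sharpness with factors in [0.7, 1.3], or
identity — so `n` augmentation types yield `n²` pair-level variants. The
inference path never calls the augmentation module; a call counter makes
that provable in tests.

## Whole-slide sweep

The sweep grid places the first epicenter at (256, 256) and advances by the
stride (default 50 px), admitting only fully in-bounds wide tiles:
`⌊(dim − 512)/stride⌋ + 1` centers per axis, row-major. A pixel is tissue
when its HSV saturation exceeds 0.07 or its value falls below 0.90; a tile
is foreground when ≥ 25 % of its narrow window is tissue. The sweep
evaluates this rule through an integral image (identical to the per-tile
rule, O(1) per cell) and classifies only foreground cells. Classification
heatmaps take the per-cell argmax with ties broken toward the lowest class
index. Probability renders scale each cell's class color linearly from
weight 1 (full color) down to weight 1/n_classes (darkest); overlays
upsample nearest-neighbour and blend `alpha·heatmap + (1−alpha)·slide`.

## Registration, fusion, quantification

Adjacent sections differ by a near-rigid placement, so the transform family
is affine (2×3, IHC-cells → H&E-cells). Initial correspondences come from
the binarized (tissue/glass) heatmaps: connected foreground components
matched across modalities by area rank (areas within a factor of two), each
contributing its centroid and four boundary extrema. The affine is fitted
with RANSAC (seeded, residual threshold 1 cell) and refined by up to three
iterations of trimmed iterative-closest-point over the component boundary
cells, keeping the best 80 % of matches per iteration. Three safeguards
make this robust when the tissue silhouette nearly fills the sweep window
and the boundary signal is weak:

* boundary cells on the window frame are excluded (the window clips tissue
  identically in both maps; those straight cut edges would anchor the fit
  to the identity);
* the ICP refit uses a similarity model (rotation + isotropic scale +
  shift) — the family section placement actually lives in — and any
  candidate far from the identity is rejected as a diverged fit, since
  adjacent sections sit nearly aligned by construction;
* all candidates (identity, RANSAC fit, each ICP iterate) are scored by
  foreground-mask agreement over interior cells, the best is kept, and a
  final Nelder–Mead pass maximizes that agreement directly over the four
  similarity parameters (a dense intensity-based polish; the simplex steps
  are sized in degrees/log-scale/cells because the objective is piecewise
  constant on the cell grid).

A manual-points override exists for pathological cases. Labels are
categorical, so warping is nearest-neighbour only; out-of-domain cells
become background.

Fusion assigns each H&E-grid cell its joint (feature class, immunostate)
and renders it through a 21-entry color table in which magenta is reserved
for microvascular proliferation coinciding with immunopositivity.
Quantification reports, per feature class i: the foreground area share
Phe(i) (per cent of H&E foreground cells, summing to 100), the cell count
Fhe(i), the intersection Ii with the aligned immunopositive area, and the
positivity share `Pi = Ii / Fhe(i)`; Pihc gives the positive/negative
shares of the aligned IHC foreground. Classes with Fhe(i) = 0 report Pi as
missing rather than dividing by zero. Area percentages use foreground
cells, not total slide area, as the denominator — glass is meaningless
tissue area.

## The synthetic slide generator

The generator emulates the statistical structure the pipeline assumes, not
tissue appearance:

* **Tissue vs. glass.** A smooth Gaussian random field, penalized within
  ~320 px of the slide border (mounted sections sit inside their glass
  margins), thresholded at the requested background fraction (default
  0.30). A second, coarser field punches interior glass holes (tears,
  large vessel lumina; ~12 % of the slide) wider than a narrow tile — they
  survive the tile-level foreground test and give every slide the interior
  silhouette structure registration anchors to.
* **Feature regions.** A nearest-seed partition with smoothly jittered
  distances (wavy boundaries); seeds are drawn from tissue pixels. The seed
  count refers to a 2048² slide and scales with area, keeping region size
  roughly constant (slides below 1536 px get at least two seeds per class,
  since with one region per class an unlucky placement starves it). Seeds
  of the immunopositive class are swapped with the deepest-in-tissue seeds,
  and any of its pixels falling in the border band not covered by
  sweep-grid cells are handed to the nearest other class: its regions carry
  a designed interior/rim positivity structure that an uncovered band would
  truncate one-sidedly. The draw is repeated until every class keeps an
  interior core (≥ 96 px from any boundary at full size) large enough for
  marking.
* **Textures.** Per-class mean color plus shared low-frequency and
  white-noise luminance modulation. Classes V and VI share the same base
  texture; class VI additionally carries dark "infiltrate" discs (radius
  36 px) on a jittered lattice. With the default spacing (200 px) and small
  jitter every narrow tile of class VI shows a disc; the ring-context
  configuration (spacing 284 px, full-cell jitter) leaves ~26 % of narrow
  tiles disc-free while ~98 % of wide tiles still see one — on that
  configuration the context path is genuinely required, which is what makes
  the bifocal-vs-subnet comparison meaningful.
* **Immunopositivity.** Within each connected region of the chosen class
  (default II), the top-f fraction of a score field — distance to the
  outer region border (interior holes filled first) plus a smooth ±12 px
  wiggle — is positive. The fraction is
  exact per region by construction, and positivity forms the interior core
  of its region: a rim stays negative, so the designed overlap fraction is
  insensitive to residual heatmap-level misalignment (a deliberate
  emulation of the full-scale regime, where features span hundreds of
  heatmap cells and boundary effects are negligible).
* **IHC slide.** The H&E-frame truth sampled through the true
  inter-section affine (rotation ≤ 3°, translation ≤ 40 px, isotropic scale
  0.98–1.02, about the slide center), rendered as DAB-brown positive,
  counterstain-blue negative, near-white glass.
* **Markings.** Uniform draws from class pixels at least 96 px (scaled on
  small slides) from any class boundary and 256 px from the slide border —
  an expert marks feature interiors, not rims.

Everything is a pure function of the spec, including its seed; identical
specs produce byte-identical slides.

### What the generator does not emulate

Nuclear morphology, stain physics and scanner artifacts, pyramidal WSI
containers, color variation between laboratories, deformable inter-section
distortion, and ambiguous or erroneous expert markings. Passing the
benchmarks therefore demonstrates that the pipeline's machinery —
extraction, learning dynamics, sweep, registration, quantification — is
correct and well-calibrated on data with known truth; it does not predict
clinical-grade accuracy on stained tissue.

## Desk-scale benchmark sizes

The benchmarks run the study regimes at sizes chosen for a single CPU:

* *Recognition*: two training slides and one held-out test slide at 2048²,
  75/60 marking dots per class per slide, tiles block-mean downsampled 8×
  (64/32 network inputs) at base width 8 with one block per stage,
  ≤ 10 epochs. The downsampling preserves the color/coarse-structure scale
  at which the texture classes live; parameter counting is unaffected by
  input size and always uses the full-width default.
* *Bifocal ordering*: the two-class ring-context task (one train, one test
  slide, 110/60 dots per class), five seeded replicates of bifocal net vs.
  narrow-only subnet with matched data, budgets and seeds.
* *Overlap recovery*: one 2560² slide pair, sweep stride 25 (finer than the
  default 50 so heatmap cells stay small relative to feature regions, as
  they are at full scale), ground-truth classifier stub, detected
  correspondences, fraction 0.75.

The deeper default stack (2, 2, 2, 2) is retained for the full-scale
configuration; at desk scale the shallow variant optimizes markedly better
under a few hundred gradient steps — an expected property of plain
(shortcut-free) deep networks, and the reason the reduced-width benchmark
uses one block per stage.

## Numerical and design choices

* Half-open `[lo, hi)` windows everywhere; 0-based pixel coordinates with
  x = column.
* Marked-epicenter extraction pads out-of-bounds pixels white (glass);
  sweep grids use only fully in-bounds tiles.
* Case-level test split takes ⌈fraction·n⌉ slides, guaranteeing a non-empty
  test set at small n.
* Probability-to-intensity mapping in renders is linear; the argmax color
  at weight 1/n_classes is darkest.
* AUC follows the rank (Mann–Whitney) convention; ties count half. Classes
  that cannot be scored (no positives, never predicted) are reported
  missing and excluded from macro averages with a warning.
* Precision and sensitivity are macro-averaged across classes, matching the
  per-class emphasis of the evaluation; this is an assumption, recorded
  here, since instance-weighted averaging is equally defensible.
* One marked coordinate yields exactly one tile pair.
* The global run seed fans out to stage seeds via an FNV-style hash of the
  stage name, so stages are independently reproducible.

## Known limitations

* The NumPy training loop is CPU-bound; full-resolution (512/256) training
  at default widths is functional but slow, and the package makes no
  attempt at GPU execution.
* Registration assumes the two heatmaps show the same tissue silhouette;
  sections with large missing pieces would need the manual-points override.
* The color-table fusion render is categorical; it does not encode
  probability confidence.
* `region_seed_count` trades region size against class balance; extreme
  values can make the interior-core requirement unsatisfiable, which the
  generator reports as an error after a bounded number of fresh draws.
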