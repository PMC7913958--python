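# bifocal

Bifocal convolutional classification of whole-slide histology images,
sliding-window feature heatmaps, and cross-modality registration, fusion
and quantification of H&E morphology against immunohistochemistry.

## The problem

A neuropathologist reading a glioblastoma slide works at two focal lengths
at once: a narrow view that identifies a structure (a proliferating vessel,
a necrotic focus) and a wider view that supplies the tissue context
disambiguating it. This package implements that idea end to end:

* **Marking-dot supervision.** Experts mark pixel coordinates of six
  morphological feature classes on H&E slides (palisading necrosis I,
  microvascular proliferation II, normal vessels III, geographic necrosis
  IV, brain tissue V, tumor background VI) and positive/negative DAB
  immunoreactivity on IHC slides. Each dot yields one *bifocal pair*: a
  512×512 context tile and a concentric 256×256 index tile.
* **The bifocal network.** Two shortcut-free bottleneck convolutional
  subnets (one per tile), global average pooling, feature concatenation,
  one softmax classification layer. The default six-class network trains
  5.6 M parameters — 24 % of a standard 50-layer residual network with the
  same head.
* **Whole-slide sweep.** A stride-50 grid from the upper-left to the
  bottom-right of the slide; every foreground tile pair is classified (no
  augmentation at recognition time) into a per-cell probability heatmap and
  its argmax classification heatmap, rendered as probability-weighted
  pseudo-color and transparent overlays.
* **Cross-modality fusion.** The IHC heatmap of the adjacent section is
  registered onto the H&E heatmap by an affine estimated from foreground
  point correspondences, warped nearest-neighbour, fused into a joint
  color map (magenta = microvascular proliferation ∩ immunopositive), and
  quantified: for each feature class *i* with heatmap area Fhe(i) and
  immunopositive intersection Ii, the positivity share is
  **Pi = Ii / Fhe(i)**.
* **Synthetic slides.** A seeded generator produces paired H&E-like/IHC-like
  slides with ground-truth label fields, a known inter-section affine, and
  a designed immunopositive fraction — so every stage is trainable and
  testable on a laptop with known truth.

## Worked example

Simulate a slide pair, train, sweep, fuse and quantify from the shell:

```
bifocal simulate --out run/sim --seed 5
bifocal train   --slides run/sim/he.png --markings run/sim/he_markings.csv \
                --out run/model --seed 5
bifocal predict --slide run/sim/he.png --checkpoint run/model/checkpoint.npz \
                --stride 50 --out run/heatmaps
```

or drive the library directly:

```python
from bifocal.benchmarks import recognition_benchmark, fusion_recovery

report = recognition_benchmark(seed=1, epochs=10)
print(round(report.macro_auc, 4))
# 0.9993

out = fusion_recovery(seed=3, positive_fraction=0.75)
print(round(out["p_ii"], 4))
# 0.733
```

The first number is the held-out macro one-vs-rest AUC of the bifocal
classifier on the six-class synthetic task (two training slides, one test
slide, case-level split): 0.9993 means the six texture classes are almost
perfectly ranked. The second is the recovered positivity share of the
microvascular-proliferation analog after the full deterministic pipeline —
sweep of both modalities, registration from detected correspondences,
warping, quantification — against a designed ground-truth fraction of
0.75: the pipeline recovers the designed overlap to within a few percent,
the residual coming from heatmap discretization and sub-cell registration
error.

```python
from bifocal.model import build_bcnn, parameter_ratio, resnet50_parameter_count

print(round(parameter_ratio(build_bcnn(), resnet50_parameter_count(6)), 4))
# 0.2387
```

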