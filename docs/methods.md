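# Methods

## Problem and pipeline

A breast tumor's molecular subtype is determined by four IHC biomarkers
read on separate slides: ER and PR (nuclear hormone receptors, Allred
scoring), Ki67 (nuclear proliferation antigen, proliferation-index bands)
and HER2 (membrane receptor, completeness/intensity scoring). The pipeline
mirrors the clinical workflow: per-biomarker semantic segmentation →
morphological cleanup and watershed instance splitting → slide-level
guideline scoring → per-patient majority voting → subtype decision. Each
stage is an independent module with its own tests; the synthetic generator
provides ground truth for all of them.

## Segmentation network

Two U-Net-style encoder–decoder pairs are chained serially ("ladder"
topology). Default geometry: depth 4, 16 filters at level 0 doubling per
level (16→256), input 240×240×3, softmax head with 3 or 4 classes.

* Feature blocks are residual: two 3×3 convolutions, each followed by ReLU
  then batch normalization, plus an identity shortcut (1×1 projection when
  channel counts change). The internal layout of the residual block is a
  design choice of this package.
* Downsampling is a stride-2 3×3 convolution; the decoder upsamples with
  2×2 stride-2 transposed convolutions.
* Each decoder block at level *l* concatenates four sources: the
  stride-2-downsampled level *l−1* encoder output, the level-*l* encoder
  output, the nearest-neighbour-upsampled level *l+1* encoder output, and
  the deconvolved level *l+1* decoder output. At boundary levels the
  nonexistent sources are simply omitted — level 0 has no *l−1* source and
  the bottleneck has no *l+1* encoder above it.
* The second encoder starts from the first decoder's full-resolution output
  and receives the first decoder's feature map at every level by
  channel-wise addition, following the ladder convention, so learning paths
  can route through either or both halves.
* Dropout (rate 0.1) is applied in decoder blocks only, on the concatenated
  skip features. Initialization is He-normal, biases zero.

The network, its layers and the Adam optimizer are implemented on a small
reverse-mode automatic-differentiation engine inside the package
(`ihcsubtype.nn`): NHWC tensors, convolutions as per-kernel-offset BLAS
matrix products, analytic backward passes for every op (verified against
central finite differences in the test suite). The engine frees
intermediate activations during the backward sweep, which keeps a full
240×240 batch-of-4 training step under ~2.5 GB.

### Batch-normalization inference statistics

Exponential running averages of batch statistics lag badly over short
training runs (tens of steps): the weights converge faster than the
averages, and eval-mode predictions degrade even on training data. After
the epoch loop, `train_model` therefore re-estimates every BatchNorm's
mean/variance as a uniform average over the training set (forward passes
only, dropout disabled) — the population-statistics definition of
batch-norm inference. Without this pass the eval-mode Dice of short runs
sits far below the batch-statistics Dice; with it the two coincide. It is
always on.

## Loss

`L = w_cce·CCE + w_ftl·(FTL₁ + FTL₂)` with defaults `w_cce = 0.2`,
`w_ftl = 0.4`, `FTLₖ = (1−TIₖ)^γ`, γ = 0.75, and Tversky weights
(FP, FN) = (0.75, 0.25) and (0.25, 0.75). Decisions taken where the
formulation leaves room:

* Soft confusion counts are accumulated **per class over the whole batch**
  (TP_c = Σ p_c·t_c etc.), the Tversky index computed per class, and the
  focal terms averaged **over foreground classes only** — the loss exists
  to protect the rare stained classes, and including the dominant
  background would dilute it. `mean_over_all` is available in `LossConfig`.
* γ defaults to 0.75; any value in (0, 1) is accepted.
* ε = 1e-6 smooths numerator and denominator (empty classes give TI = 1,
  contributing zero focal loss) and clips CCE probabilities.
* The analytic gradient floors (1−TI) at 1e-12 before raising to γ−1,
  since the derivative of the focal term diverges at perfect overlap.

## Synthetic slides

The generator emulates hematoxylin/DAB appearance well enough to exercise
segmentation, counting and scoring: whitish background (235, 230, 225),
violet immunonegative nuclei (120, 90, 170), solid dark-brown strong
positives (110, 70, 40), faint-brown weak positives (170, 130, 90), and for
HER2 brown membrane arcs (intense (90, 55, 30) / faint (170, 130, 95))
drawn as annuli around blue-violet nuclei, subtending completeness·360°
from a random start angle. Nuclei are rotated ellipses with radii uniform
in 8–12 px; per-nucleus color jitter plus Gaussian pixel noise (σ = 5) are
added; all values are configurable. Placement is rejection sampling with a
minimum separation (2 px) and an optional overlap budget used to exercise
watershed splitting; an attempt budget turns impossible packings into a
`CapacityError`.

The default ER/PR configuration chooses nucleus counts so the expected
class-pixel ratio background:strong:negative:weak matches the 141:14:6:1
imbalance of real ER slides; at the nominal 1440×1920 slide size this gives
roughly 761 strong, 326 negative and 54 weak nuclei. Ki67 defaults to ~1
nucleus per 3500 px² with 30% positives; HER2 to ~1 per 9000 px² so
membranes stay separable.

Cohorts assign each patient a biomarker-status tuple and sample per-slide
mixtures that land **safely inside** the corresponding scoring bins
(e.g. ER-positive slides draw a 45–62% positive fraction with 78–90%
strong, Ki67 bands are realized by integer counts checked against the exact
band edges, HER2 scores map to completeness ranges 0–0.05 / 0.25–0.6 /
0.95–1.0 and faint/intense). This margin is what lets end-to-end tests
demand *exact* truth-table recovery: with clean masks, discretization and
watershed effects cannot push a slide across a bin boundary. Seeds derive
from a single master seed, so cohorts are bit-reproducible.

What the generator does **not** model: stain variation and color bleed,
texture inside nuclei, tissue architecture, out-of-focus regions, membrane
fragmentation, and touching nuclei chains. Passing tests therefore
demonstrate the correctness of the pipeline's logic and the learnability of
the architecture, not clinical performance on real slides.

## Post-processing and scoring

Per-class binary opening then closing with disk radius 1, then a
minimum-object-size filter (30 px at model resolution). Watershed on the
Euclidean distance transform with `peak_local_max` markers
(`min_peak_distance` = 8 px, the generator's minimum nucleus radius);
components left markerless are kept as single instances so the instance
pixels always partition the foreground. The HER2 membrane class is cleaned
but not split — membranes are rings, and instance counting applies to
nuclei only.

HER2 completeness casts 360 one-degree rays from the nucleus centroid and
checks for membrane pixels within 5 px beyond the nucleus boundary (both
radii configurable). Membrane intensity uses the mean optical density
−log₁₀(I/255) of the membrane pixels thresholded at 0.40 by default; a
trainable shallow CNN classifier (`ihcsubtype.intensity`) is the learned
alternative. The HER2 rule table is: ≥10% of cells with completeness ≥ 0.9
→ 3+ if intense else 2+; otherwise ≥10% of cells with completeness ≥ 0.1 →
1+; else 0. Allred proportion bins, the TS ≥ 3 positivity rule, Ki67 band
edges (14/21, boundaries inclusive to intermediate) and all HER2 thresholds
live in `ScoringConfig`.

Two scoring details are package decisions: the Allred intensity score is
the count-weighted mean of weak (=1) and strong (=3) nuclei rounded half-up
to {1,2,3} (the segmentation has no separate "intermediate" intensity
class), and a Ki67 "intermediate" groups with "low" for the Luminal A/B
split. An equivocal HER2 (2+) yields an explicit indeterminate subtype call
("reflex testing advised") unless configured to coerce to negative. Ties in
the per-patient majority vote break by fixed clinical priority (pos > neg,
high > intermediate > low, higher HER2 score first).

## Training and evaluation

Adam (lr 0.001), batch size 4, dropout 0.1, L2 1e-5 on convolution kernels
(the coefficient is not specified by the scoring guidelines or the
architecture; 1e-5 is the package default), no augmentation, no early
stopping; models train for the configured epoch count exactly.
Cross-validation is leave-one-patient-out: every fold holds out all slides
of one patient, asserted disjoint in the tests. The four biomarker models
are fully independent.

Pixel metrics are confusion-matrix precision/recall/Dice per class; object
metrics use greedy one-to-one matching by descending IoU with threshold 0.3
(a package default — no clinical standard prescribes the criterion).
Undefined ratios are reported as 0 with an explicit `defined` flag rather
than NaN.

## Problem sizes in the tests and acceptance script

Full-scale defaults (1440×1920 slides, 15 patients × 10 slides per
biomarker, 50 epochs) match the nominal study conditions; the test suite
and `scripts/acceptance.py` run the same code paths at smoke scale so a
complete run stays in the minutes range on one CPU: cohorts of 15 patients
× 2 slides at 240×320 for the oracle-bypass check, and a 20-slide
easy-contrast Ki67 set at 240×240 trained for 8 epochs (batch 4) for the
learning check, evaluated on a 5-slide held-out patient. The 8-epoch
budget was chosen for runtime; convergence on this contrast-separable task
occurs within the first few epochs.

## Known limitations

* The numpy engine is single-threaded BLAS; full-scale training (1680
  patches × 50 epochs) is possible but slow — the package's scope is the
  method, its correctness, and desk-scale experiments.
* Synthetic colors are plausible stand-ins, not calibrated to any scanner
  or stain protocol; no claim transfers to clinical slides without
  retraining and validation.
* Membrane completeness assumes roughly convex nuclei (ray casting from
  the centroid).
* The imbalance-faithful ER defaults produce dense slides; very small
  synthetic slides need reduced nucleus counts or radii to remain packable.
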