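# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `paintcog`. It is the package's own account of its
science; every number quoted as a result here is computed by the test suite
or by `scripts/acceptance.py`, not asserted.

## The measurement problem

A coloring task gives every subject the same outline template and a fixed
set of 12 colored pens. The finished paintings carry two kinds of signal
relevant to chronic schizophrenia: *which and how many colors* the subject
chose, and *how the strokes were laid down* (length, direction, position).
`paintcog` quantifies both, tests for group differences between patients
(SCZ) and healthy controls (HC), learns a diagnostic classifier directly
from pixels, and regresses symptom severity (PANSS) on the images.

## Color features

The RGB cube is partitioned uniformly into 4 levels per channel, giving
64 cells; `quantize_rgb(r, g, b) = 16⌊r/64⌋ + 4⌊g/64⌋ + ⌊b/64⌋`. A
painting's color signature is the pixel count per cell (histogram
conservation: counts sum to width x height). The partition is the canonical
"64-bin RGB histogram"; no perceptual space is used.

`colors_used` counts occupied cells after excluding the white-canvas cell
(63) and the black-outline cell (0), because unpainted canvas and template
outlines would otherwise dominate. The exclusion set is a parameter.

Group association is mass-univariate: per cell, the point-biserial
correlation (Pearson with 0/1 group coding, patient = 1) of counts against
the label, p-value from the exact t transform at n−2 df, masked at an
uncorrected alpha (default 0.05). A Benjamini–Hochberg q-value column is
reported alongside; cells with zero variance across subjects are flagged
undefined and excluded from the mask. The background cell legitimately
correlates *positively* with patient status (patients paint less), so
direction claims about pen colors should exclude cells 0 and 63.

## Stroke features

Strokes are straight line segments, so the Hough transform in Hesse normal
form `r = x·cosθ + y·sinθ` is the natural signature. Coordinates are
pixel-based, x = column, y = row, origin top-left; θ ranges over [−90°,
90°) (default step 1°) and r over [−D, D] (default step 1 px) with D the
image diagonal. Every edge pixel votes once per θ bin into the nearest r
bin, so total votes equal (edge pixels) x (θ bins) exactly.

Numerical choice: r is quantized to 1e-9 px before binning. On an integer
pixel grid, angles such as ±30°, ±60° and ±90° produce r values exactly
halfway between bin centers; without quantization the winner depends on
floating-point association order. After quantization, knife-edge ties are
exact and break toward the smaller r, and the vectorized accumulator is
bin-for-bin identical to a brute-force nearest-center enumeration (this is
asserted exactly in the tests on ≤32x32 fixtures).

The edge detector is a 3x3 Sobel gradient magnitude on Rec.601 luminance
with a relative threshold (default 0.2 x image maximum); a uniform image
yields an empty edge map, and an empty map a zero accumulator with a
"no-peak" result. The accumulator argmax breaks ties by smallest θ, then
smallest r.

Group comparison runs a pooled two-sample t-test per accumulator cell
(vectorized, identical arithmetic to the scalar kernel), with both a fixed
p < 0.001 mask and BH q-values, plus a point-biserial correlation map
masked at |r| ≥ 0.3. All images must share dimensions so accumulator bins
align across subjects. In pseudocolor renderings of the mean accumulator,
θ is on the x-axis and r on the y-axis.

## Statistical kernel

Pooled-variance (Student) two-sample t with df = n₁ + n₂ − 2, computable
from raw samples or published (n, mean, SD) triples — the two forms are
algebraically identical and tested as such. Pearson chi-square on 2x2
tables without continuity correction. Both choices reproduce, from printed
summary inputs, the demographic comparisons the package's worked examples
use (t = 2.790 for age, χ² = 1.949 for sex); Welch's t and the Yates
correction are available behind flags. P-values are two-sided throughout.
Benjamini–Hochberg is the step-up rule q(i) = min over j≥i of m·p(j)/j,
capped at 1. RMSE is the plain root mean square difference.

## Networks

PyTorch is not assumed: `paintcog.nn` is a small NumPy layer library with
explicit backpropagation (im2col convolutions, batch normalization,
rectifiers, max/average/global-average pooling, fully connected layers,
Adam, cross-entropy and MSE losses). Everything is float32 NCHW and
deterministic given the seed. Backward passes are verified against
finite-difference directional derivatives, and the convolution forward
against SciPy's 2-D cross-correlation.

### Residual classifier

Residual blocks follow the pre-activation arrangement
`y = x + F(x)` with `F = BN–ReLU–conv3x3–BN–ReLU–conv3x3` and a strided
1x1 projection shortcut when the shape changes. With the residual branch
zeroed, an identity-shortcut block is the identity map *exactly* — the
post-sum rectifier of the original arrangement would break this, which is
why the pre-activation form was chosen.

Two variants: `resnet18` (7x7/2 stem, 3x3/2 max-pool, four stages of two
basic blocks at widths 64/128/256/512, global average pool, 2-neuron
head; input 224x224x3) and `small` (3x3 stem at width 8, one
identity-shape block, one strided block to width 16, pooled head) for
CPU-scale training. Tie logits resolve toward the control class.

The classification protocol: per class, draw train/test subjects uniformly
without replacement (defaults 20/15 HC, 266/15 SCZ), duplicate each
healthy training subject 13x (plain duplication — the arithmetic
20 x 13 = 260 dictates it; photometric augmentation exists behind a flag
and is off by default), never touch the test set, train with
cross-entropy, evaluate a patient-positive confusion matrix, and repeat
the whole cycle with re-drawn splits, reporting per-run accuracies with
mean and SD (SD is the n−1 sample SD; a single run reports SD 0).
Training hyperparameters default to the regression recipe below since no
classification-specific recipe is published; all are configurable.

### Score-regression network

The fixed topology (input 224x224x3): BN → conv 8x8/4 → 55x55x8 → BN →
conv 3x3/2 → 27x27x16 → BN → conv 3x3/2 → 13x13x32 → average-pool
3x3/2 pad 1 → 7x7x32 → fully connected → scalar. Kernel geometries are
not printed anywhere authoritative; these are the minimal conventional
choices that realize every printed output size, and the build function
hard-asserts the realized shapes. Batch normalization *precedes* each
convolution, following the printed layer order. A rectifier follows each
convolution by default (`relu=False` gives the literally printed, purely
linear stack, which would make the depth pointless). The loss is plain
MSE.

Training recipe (defaults): Adam, 30 epochs, initial rate 0.01, minibatch
128 (clipped to the training-set size), piecewise schedule halving every
10 epochs, L2 coefficient 0.005. One independent network per target (P,
N, G, total). Subjects with missing PANSS are excluded; the remainder
split 3/4 train (floor) / 1/4 test.

Two numerical choices matter on short CPU schedules:

- **Target standardization.** Targets are z-scored with training-set
  statistics and predictions mapped back. With raw scores (means 10–60)
  the published learning rate cannot move the output bias to the data
  scale within 30 epochs; standardization preserves the recipe while
  making it usable. RMSEs are always reported on the raw score scale.
- **Batch-norm recalibration.** After training, one momentum-1 pass over
  (up to 512) training images replaces the exponentially averaged running
  moments with the realized activation moments. Short schedules otherwise
  leave eval-mode statistics far from the trained regime, which visibly
  corrupts held-out predictions.

## Synthetic cohort generator

The generator states a world matching the study design and the reported
effect directions; it is the fixture for every downstream stage.

- **Template**: abstract closed regions (axis-aligned rectangles with 1-px
  black outlines, ≥2-px clearance) on a white canvas, default 224x224 so
  no resize is needed downstream. The analyses never use template
  semantics, so no bird/tree/flowers artwork is reproduced.
- **Palette**: 12 named pen colors, each in its own histogram cell,
  distinct from the background (cell 63) and outline (cell 0) cells, so
  color counts are identifiable.
- **Subjects**: patients use fewer distinct colors (mean 5 vs 9, SD 1.5,
  truncated to [1, 12]); patient strokes are shorter (mean length 22 px vs
  45), more disordered (angular SD 55° vs 12° about horizontal), more
  central (anchor-in-central-disk probability 0.65 vs 0.15), and fewer
  (70 vs 90) so patients paint fewer pixels overall, consistent with
  shorter lines. Ages are Gaussian at the reported group means/SDs,
  female fractions at the reported proportions.
- **Rendering**: strokes are straight segments 1–3 px wide through an
  anchor pixel, clipped to the anchored region's interior; a fix-up pass
  guarantees that exactly the drawn number of distinct colors is present.
- **PANSS**: each subscale is intercept + weights · (n_colors, mean
  length, angular dispersion, center bias) + Gaussian noise (SD 4),
  rounded and clipped to [7,49]/[7,49]/[16,112]; total = P + N + G
  exactly. Default weights place patient subscale means near the reported
  ones (≈11.3/16.5/27.5). Scores are missing with probability 37/281.
- **Reproducibility**: one master seed; each subject's substream is
  seeded by (master seed, CRC32 of subject id), so regeneration is
  byte-identical and independent of generation order.

What the generator does **not** emulate: scanner noise and illumination,
curved or overlapping naturalistic strokes, template semantics, education
and cultural covariates, and any coupling between color choice and stroke
geometry beyond the group means. A green test on this world therefore
establishes that the pipeline recovers effects of the stated form at the
stated sizes — not that the original clinical effect sizes are
reproduced, which would require the original paintings.

## Design decisions that were genuinely open

- The study reports 281 patients for classification but 246 in the
  demographic table without explanation; cohort sizes are configuration,
  and the defaults follow the classification design (35/281) while the
  demographic worked examples use the printed 246-based summaries.
- Whether the published stroke-map threshold is "p < 0.001" or "BH FDR"
  is ambiguous in the source; both are computed, the headline mask is the
  fixed threshold.
- Whether the background cell belongs in the per-color tests is unstated;
  it is included in the tests but excluded from `colors_used`.
- The education-years comparison cannot be reproduced because the
  underlying category table is not published; it is out of scope.

## Limitations

- Training is single-threaded NumPy; the `resnet18` variant is provided
  and tested structurally but is not practical to train at 224x224 on one
  CPU. The `small` variant is the desk-scale workhorse.
- Accuracies near 100% on the separable synthetic world say nothing about
  the clinical 90.33%; that number lives on unavailable data.
- The regression network beats a mean predictor on strongly
  image-determined synthetic scores; with the default noisy score model
  (SD 4 around weak feature effects) it does not reliably do so at small
  n, which is the expected behavior of a weak signal, not a defect.
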