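# Methods

This note records the scientific and numerical choices behind `cxrtrust`:
what each layer computes, which parameters matter, what the synthetic
fixtures do and do not emulate, and where the design was genuinely open.

## Labels and imbalance machinery

Annotations arrive one bounding box per row; aggregation to image-level
targets is by set semantics (y_c = 1 iff any box of class c exists), so
duplicate boxes are idempotent. The class order is frozen with
"No finding" at index 14; an image whose rows mix "No finding" with
abnormality boxes is contradictory, and the default policy keeps the
abnormalities and zeroes the normal label with a warning (a strict mode
raises instead).

Positive-class weights are w_c = N_c⁻/N_c⁺ on the training split, clipped
at 20 to stop rare findings (sub-1% prevalence) from dominating gradients.
A class with no training positives receives the clip value so the loss
stays finite on degenerate subsets.

The stratified splitter is a greedy iterative stratification over label
sets: repeatedly take the label with the fewest unassigned positives and
deal its examples to the split with the largest remaining per-label demand
(ties by remaining overall capacity, then the seeded generator). This
preserves marginal prevalence to within a few examples per class; it makes
no attempt to preserve exact co-occurrence pair counts, which would require
a much more expensive optimisation and is not needed by anything
downstream. Published overall split sizes depend on the original
(unpublished) seed and implementation, so only marginal-prevalence
tolerance is asserted, not exact per-split counts.

Mixup draws one λ ~ Beta(α, α) per batch (α = 0.2, applied with
probability 0.3) and mixes images and targets with the same λ; the BCE loss
accepts the resulting soft targets. The permutation may fix points; at
realistic batch sizes the identity permutation has negligible probability
and a fixed point simply reproduces the unmixed sample.

## Anatomy masks and derived regions

RLE masks are decoded with an explicit dialect (row/column-major flattening,
0/1-based starts) because public releases disagree; the default is
column-major 1-based. Derived regions:

* apical/basal split the lung mask at the midpoint of its own occupied
  rows, r_mid = ⌊(r_min + r_max + 1)/2⌋ — the mask's vertical extent, not
  the image midline, so a low- or high-riding lung field still splits in
  half;
* the pleural band is lungs minus their erosion by a disk (default radius
  8 px at 384², scaled proportionally with resolution and floored at 2 px —
  a 1-px annulus degenerates under nearest-neighbour resampling);
* the near-heart band is a dilation annulus (same default radius) around
  the heart, disjoint from the heart by construction. The peri-cardiac
  band stands in for "near the mediastinum" throughout; no separate
  mediastinal mask is modelled.

Region sets validate their invariants on construction (unions, partition of
lungs, band containment). Masks are re-binarised at 0.5 after any resize;
regions are derived at the working resolution after image resize, so band
widths are consistent with the saliency grid.

Preprocessing follows the fixed order invert → Gaussian blur → CLAHE →
bilinear resize, emitting an 8-bit-range image. Inversion reflects
intensities within the observed range (MONOCHROME1-style data); CLAHE is
skipped on zero-dynamic-range inputs so a flat field stays flat.

## The hybrid scaffold

The scaffold is a deliberately tiny two-branch classifier exposing exactly
the tensors the post hoc layers need: a three-stage stride-2 CNN producing
a pre-attention map f_cnn (stride 8, e.g. 8×8 at a 64² input), a serial
channel→spatial attention block (bottleneck ratio 16, 7×7 spatial kernel,
sigmoid gates; gates can be clamped to 1 as an ablation hook) producing
a_cnn, global average pooling to v_cnn, a small patch-token branch (16×16
patches, class token, learned positional encodings, 2 encoder layers)
producing v_vit, the fused embedding v_hyb = [v_cnn ‖ v_vit] used for
Mahalanobis scoring, and a linear head to 15 logits.

It runs on the package's own reverse-mode autodiff engine (numpy tensors,
float64, eager tape). One numerical point deserves record: softplus must be
a primitive with derivative σ(x). Composing it from relu and log-exp terms
introduces an artificial kink at x = 0 where both relu subgradients vanish,
which silently zeroes all gradients when the head starts at exactly zero
logits.

Training (Adam, warm-up + cosine per epoch, EMA of weights, early stopping
on validation macro-AUROC with patience 7 and min-delta 0.001) includes a
*branch dropout* option: with probability 0.5 per batch the token branch is
zeroed. Without it the position-aware token branch absorbs the whole
classification signal on the synthetic task and the convolutional head
weights for some classes become non-positive — their Grad-CAMs are then
identically zero because the ReLU floors negative channel contributions.
Branch dropout forces the convolutional pathway to classify on its own,
keeping its saliency class-discriminative. Warm-up starts at base_lr/warmup
rather than 0; the cosine anneals per epoch to ~0 at the final epoch. The
anatomy penalty λ‖A ⊙ (1−M)‖_F is implemented and tested but defaults to
λ = 0, the setting under which image-level supervision alone is used.

## Saliency and localisation

Grad-CAM and Grad-CAM++ are computed from the same forward pass for either
feature source (pre- or post-attention), so source comparisons isolate the
attention refinement. The top-p threshold τ_p is realised as the k-th
largest heatmap value with k = ⌈p·H·W⌉ and ties included — deterministic
and exactly reproducible, rather than an interpolated quantile. A constant
raw map has no min–max normalisation and collapses to an all-zero heatmap
flagged `degenerate`. After bilinear upsampling the map is re-normalised to
span [0, 1] (interpolation pulls the peak slightly below 1). IoU with an
empty union is defined as 0; boxes are rasterised as filled rectangles and
unioned before IoU.

A known limitation, observed directly on the synthetic task: findings the
model represents as an activation *deficit* (lucencies — e.g. air where
tissue should be — classified via negative head weights on bright-tissue
channels) are structurally invisible to ReLU-floored gradient CAMs. The
synthetic pneumothorax therefore carries a bright ridge texture standing in
for the sharp pleural-line signature, which the convolutional channels
detect as positive evidence; on real radiographs the same failure mode
should be expected for purely lucent presentations.

## Fuzzy reasoning

Evidence components are fractions of the top-p pixels inside each region
(an energy-weighted variant is available behind a flag). Memberships are
piecewise-linear ramps. Breakpoints are not externally prescribed; the
defaults are ramp_up(0.2, 0.6) for area regions (inside, heart, apical,
basal), ramp_up(0.5, 0.9) for probability, and ramp_up(0.05, 0.25) for the
two thin-band regions (pleural rim, peri-cardiac annulus). The band-specific
scaling is geometric, decided from the region definitions rather than any
measurement: an annulus of width w around a structure of scale R occupies
only ~w/R of any area-proportional saliency mask (a few percent at the
default radii), so an activation-fraction threshold of 0.2 would be
unreachable by construction. AND is the product t-norm (order-invariant),
OR the probabilistic sum folded left, NOT the complement; the class support
is the maximum rule activation, with the winning rule recorded for
narratives. "No finding" has no spatial pattern; its rule is ramp_down over
the *maximum abnormality probability*, supplied by a helper. Composite
concepts (cardiomegaly_with_effusion) assert when every member exceeds both
a probability and a support threshold (defaults 0.5/0.5). The ontology
export is a lightweight class hierarchy with annotation properties in
Turtle — description-logic inference is out of scope.

## OOD detection

All logarithms are natural. The energy score is computed in a log-sum-exp
stable form and satisfies s_energy(z + c) = s_energy(z) − c exactly.
Feature statistics use the population (1/n) variance; ε = 10⁻³ sits inside
the per-dimension denominator, and the distance is the square root of the
normalised sum (a 1-D feature one standard deviation from the mean scores
≈ 1). Thresholds are linear-interpolation empirical quantiles of the ID
calibration scores (5th percentile for confidence, 95th otherwise), so each
detector flags ≈5% of its own calibration set by construction and the OR
union flags at most 20% (union bound; in practice less because the flags
correlate). For benchmarking, detectors are oriented so larger = more OOD
(confidence negated); AUROC is the tie-corrected rank statistic, AUPRC
takes OOD as positive, and FPR95 is the ID flag rate at the largest
threshold keeping OOD TPR ≥ 0.95 (step-function convention).

One analytic point: a purely directional mean shift of size s in a
D-dimensional unit-variance feature space gives projection AUROC Φ(s/√2),
but the omnidirectional Mahalanobis *distance* statistic dilutes it
(noncentral- vs central-χ² radii), so the distance detector's AUROC is
strictly between chance and the projection bound. Tests assert both.

## Multi-label evaluation

Per-class AUROC is the midrank Mann–Whitney statistic (equal to pairwise
comparison with half credit for ties, asserted against brute force).
Degenerate classes (no positives or no negatives) are excluded from the
macro average and flagged. Micro-AUROC ranks the flattened label/probability
pairs. The bootstrap resamples images (rows) with replacement, 2000
replicates by default, percentile 2.5/97.5 bounds and replicate standard
error; replicates that make a class degenerate are redrawn up to 100 times,
then skipped and counted. Decision thresholds are fitted per class on
validation data by F1 maximisation over the midpoints of consecutive
distinct scores (every achievable confusion table is visited) and applied
unchanged to test data; precision with no positive predictions is reported
as 0 with an explicit flag; macro-F1 is the mean of per-class F1 and a
pooled micro row is also emitted.

## Synthetic fixtures: what they emulate, and what passing tests show

The generators are pure functions of (seed, parameters) and emulate the
*structure* of the real task, not its appearance:

* **Anatomy** — two lateral elliptical lungs and a medial inferior cardiac
  ellipse with ±4% jittered axes on a noisy background (lungs brighter than
  soft tissue); all derived-region invariants hold by construction.
* **Cases** — one additive Gaussian lesion per requested finding, placed in
  the finding's characteristic zone (basal pleural band for effusion,
  apical pleural band for pneumothorax, the cardiac silhouette for
  cardiomegaly, free parenchyma for nodules/opacities) with a
  class-specific shape: a wide flat band (σ = 0.09/0.18 of the image side),
  a tall narrow ridged stripe (0.15/0.08, ridge period 0.08), a round
  cardiac blob (0.13/0.13), a compact bright nodule (0.115/0.115,
  amplitude 0.7 vs 0.55). Sizes put the ground-truth box (bounding box of
  the >20%-of-peak support) at roughly 15–20% of the frame, the same budget
  as the default top-p = 0.20 mask, so localisation quality is measurable
  on the IoU scale. The emitted box encloses the lesion support exactly.
* **Label matrices** — exact positive counts at requested prevalences, the
  normal label filling lesion-free rows.
* **Score suites** — ID logits with one dominant class per sample
  (confident single-finding predictions) vs shrunk-toward-zero OOD logits;
  features standard normal vs mean-shifted by 3.0 along the unit diagonal,
  so the projection AUROC has the closed form Φ(3/√2) ≈ 0.983. Cohort sizes
  default to 400 + 400, matching a balanced wrong-study benchmark.
* **Fixture model** — a 64²-input scaffold (16 CNN channels, 16-dim tokens)
  trained on 300 cases for 100 epochs at base_lr 10⁻², EMA decay 0.98
  (matched to the ~2000 optimisation steps at this scale; 0.9995 is the
  full-scale default). The fixture trains its whole budget: the ranking
  metric saturates early while CAM spatial sharpness keeps improving, so
  early stopping would return immature saliency. Training takes about a
  minute on one CPU.

Passing tests on these fixtures demonstrate that the machinery is
implemented correctly — that saliency, evidence, rules, scores, thresholds
and metrics compute what they claim on inputs with known ground truth. They
do not demonstrate radiographic performance: real chest films have texture,
projection geometry, co-occurring findings, annotation noise and domain
shift that the additive-blob world deliberately omits.

## Problem sizes used by the test suite and acceptance script

Fixture training 300/60 images at 64²; localisation suites 75 cases (60
with boxes); Gaussian separability n = 5000 per cohort; calibration and
benchmark cohorts 400 + 400; bootstrap 2000 replicates at N = 100 and 400.
These sizes were chosen so the whole pipeline, including model training,
runs end to end on a single CPU in a few minutes while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

* Gradient CAMs cannot show deficit-coded (lucent) findings, as above.
* The fuzzy rule base and membership breakpoints are hand-crafted; nothing
  is learned from data, and support scores inherit any miscalibration of
  the breakpoints.
* The apical/basal split is a coarse two-zone model; real zonal reporting
  uses three zones per lung.
* The scaffold is a functional stand-in, not a performant classifier;
  its numbers say nothing about full-scale backbones.
* The OOD layer assumes the calibration cohort is clean in-distribution
  data; contamination shifts every quantile threshold.
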