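# Methods

`gonscreen` implements a two-branch screening system for glaucomatous optic
neuropathy (GON) on color fundus photographs, together with a synthetic image
generator that makes every stage verifiable against analytically known
geometry. This note records the model, the tunable parameters that matter,
the numerical choices, and what the synthetic experiments do and do not show.

## The screening model

A fundus photograph passes through five stages:

1. **Preprocessing.** Per-channel percentile normalization maps the (1st,
   99.9th) intensity percentiles onto [0, 255], compensating exposure
   differences between captures, followed by unsharp masking
   (`out = img + amount · (img − G_σ(img))`, default σ = 5 px at ROI scale,
   amount = 1) to enhance the disc margin and vessel tree. The high
   percentile is 99.9 rather than a more usual 99 because the disc and cup
   together occupy only a few percent of a fundus frame; clipping the top 1%
   of intensities flattens exactly the structures the pipeline measures.
2. **ROI extraction and quality gating.** The optic disc is located in the
   median-smoothed red channel: Otsu binarization, closing and hole filling,
   then the centroid of the connected component with the largest integrated
   red intensity (so a dimmer decoy loses to the true disc even at equal
   size); if no disc-scale component exists (area < 1000 px) the locator
   falls through to the image center and the validity gate rejects the crop.
   A windowed-brightness argmax was tried first and abandoned: its response
   plateaus whenever the window and disc sizes mismatch, wandering tens of
   pixels. A fixed 256×256 crop is taken around the located center (center ↦
   index 128, 0-based, half-open; crops shifted minimally to stay in
   bounds). The crop is accepted only if the Otsu-binarized red+green
   composite projects to a prominent peak near the crop center on both axes:
   both peaks within 32 px of center (12.5% of the ROI) and both prominences
   ≥ 0.2 × the maximum possible column sum. Prominence is peak height above
   the profile median. Rejected crops are reported "ungradable" and never
   reach a classifier; evaluation counts them separately.
3. **CNN branch.** A conv net over the preprocessed ROI. All convolutions
   are 3×3; the trunk ends in global average pooling (GAP) followed by a
   single fully connected layer to two logits and softmax. This head shape
   is a hard architectural contract because class activation maps project
   the FC class weights back onto the feature maps entering GAP. The
   `small_default` backbone (4× average-pool stem, conv widths 16/32/64/64
   with 2× max-pools between) trains on a few hundred ROIs in minutes on one
   CPU core; `vgg_like` (double-conv blocks, widths 32/64/128/128) is
   provided for real data. Training is SGD with momentum 0.9 on
   cross-entropy, default learning rate 0.01, batch 16, dropout 0.5 before
   the FC layer, and geometric augmentation (rotation ≤ 10°, shift ≤ 5%,
   shear ≤ 4°, zoom ≤ 8%) active in training only. Inputs are scaled to
   [0, 1] and centered at 0; centering matters — with uncentered inputs the
   early optimization intermittently stalls at chance for many epochs.
   The max-class softmax probability is the decision's confidence score.
4. **CDR/SVM branch.** Classical channel separation recovers the three
   morphometric features: vertical cup-to-disc ratio (CDR) and the
   superior/inferior rim-to-disc ratios. Vessels are removed per channel by
   detecting them with the black top-hat of a grayscale closing (disk radius
   7 px, wider than any vessel; pixels brightened by > 20 intensity units)
   and replacing each vessel pixel with the nearest unobstructed value —
   closing alone overwrites a small cup with rim intensity once vessels
   cover most of it, while nearest-neighbor fill lets the surviving cup
   pixels propagate inward. The disc margin comes from the red channel
   (Otsu threshold → largest component → fill holes); the cup comes from
   the green channel: subtract the scalar mean + SD of the ROI's green
   intensities, clip negatives, erode the disc interior by 4 px (the
   blurred dark ring at the disc margin must not enter the clustering, or
   with a small cup K-means splits boundary-vs-rim instead of rim-vs-cup),
   split the remaining intensities with K-means (K = 2, scalar intensity
   feature, k-means++ with fixed seed, 10 restarts), take the higher-mean
   cluster (label-permutation safe), close then open the mask (radii 5 and
   3 px — closing first, because residual vessel shadows can cut a small
   cup into fragments that opening alone would erase) and keep the largest
   component intersected with the disc. Vertical diameters are read along the vertical meridian
   through each component's own centroid column; the three ratios are
   re-normalized to sum to exactly 1. An RBF SVM with per-feature
   standardization classifies the triple; C and gamma come from an
   exhaustive grid search (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1, 10})
   by stratified cross-validated accuracy, and the winner is refit with
   Platt-calibrated probabilities so this branch emits the same decision
   record as the CNN.
5. **Confidence-gated ensemble.** The CNN label is final when its confidence
   is ≥ θ; strictly below θ, the SVM decides on the image's features. The
   gate exists to avoid missing moderate-to-advanced disease, which
   inevitably shows an enlarged CDR. θ defaults to 0.85 and can be selected
   by sweeping θ over 0.50, 0.55, …, 1.00 (11 values) on validation records
   and maximizing sensitivity + specificity (Youden-style), ties resolving
   to the lowest θ (least SVM involvement). The sweep runs on a validation
   split carved out of the training set, never on test data.

**Evaluation** treats glaucoma as the positive class throughout: accuracy,
sensitivity, specificity from the confusion matrix over gradable images;
ROC by threshold sweep with trapezoid AUC and a stratified bootstrap 95% CI
(default 2000 resamples); stratified train/test splitting with
largest-remainder rounding; stratified 5-fold cross-validation (80–20 per
fold), selecting the best-validation-accuracy fold.

## Numerical and design choices

- **Cup-statistic scope.** The mean + SD subtracted before cup clustering is
  computed over the whole ROI's green channel, not over in-disc pixels only.
  A scalar in-disc statistic self-destructs once the cup covers more than
  about half the disc area (mean + SD then exceeds the cup intensity and the
  clip zeroes everything) — precisely the advanced-glaucoma regime. With the
  ROI-wide statistic the subtraction removes background and the K-means
  split genuinely separates rim from cup at any cup size.
- **Raw-crop segmentation.** The feature branch segments a raw-intensity
  crop taken at the located center, while validity gating and the CNN
  consume the preprocessed crop. Channel segmentation derives its own
  statistics, and percentile normalization of a full frame can saturate the
  disc interior.
- **Degenerate clustering.** If the in-disc transformed intensities span
  less than ~4 intensity units, or the two K-means centers are closer than
  that, the cup is declared empty (CDR 0) with a warning rather than an
  exception; the geometry then reports rims covering the whole diameter.
- **Decision tie-break.** `p_glaucoma = 0.5` classifies as glaucoma —
  screening errs toward referral. "Below threshold" is read strictly:
  confidence = θ stays with the CNN.
- **Grid-search tie-break.** On cleanly separable feature sets every
  (C, γ) scores 1.0; ties resolve to the largest C then γ, because an
  underfit SVM's near-zero decision function leaves Platt calibration
  uninformative.
- **Segmentation-failure fallback.** If the gate routes to the SVM but
  features are unavailable (segmentation failed), the CNN label stands,
  flagged, so the pipeline is total over gradable images.
- **Determinism.** One run seed drives dataset generation, splits, weight
  init, shuffling, dropout, augmentation, K-means and bootstrap through
  spawned `SeedSequence` streams; reruns are byte-identical.

## The synthetic generator

Each image renders a dark reddish background, a bright elliptical disc
(red-channel dominant everywhere inside the disc), a brighter inner cup
(green-channel elevated only inside the cup), 2–5 px dark vessel polylines
crossing the disc, then global brightness gain, Gaussian blur and additive
Gaussian per-channel noise, clipped to [0, 255]. Ground-truth masks are the
pre-noise geometry. The cup's vertical semi-axis is `cdr_true · r_v` and its
center is placed so that superior rim + cup + inferior rim equals the
vertical disc diameter exactly, with `rim_split` fixing the superior share;
the cup's horizontal semi-axis is 0.85 of a proportional width, reflecting
the vertical elongation of glaucomatous cupping.

Dataset defaults mirror the screening cohorts such systems are built on:
discs of vertical radius 42–58 px in a 512×512 frame, glaucomatous CDR drawn
from 0.65–0.95 and normal from 0.25–0.55 (group means near 0.80 vs 0.42),
near-symmetric rims for normals and rim-split 0.3–0.7 for glaucoma (focal
rim thinning), gain 0.85–1.15, blur 0.5–1.2 px, noise SD 4–10. Invalid
captures place the disc near an image border (≥ 25% of the frame width from
center, so a clamped crop cannot center it) or omit it entirely.

The cross-camera experiment uses a "style B" preset (gain 0.55, blur 3.0,
noise SD 25) emulating a dimmer, softer, noisier second camera; its ROIs are
taken without brightness normalization so the style difference actually
reaches the classifier, mirroring deployment against an uncorrected new
source.

**What passing tests show — and what they do not.** The synthetics exercise
the pipeline's logic: channel contrast recoverable by construction,
separable classes, known geometry. Real fundus photographs add peripapillary
atrophy, hemorrhages, media opacity, camera vignetting, and continuous
disease severity; none are modeled, so synthetic accuracies say nothing
about clinical performance. CDR recovery error (≈ 0.01 mean on the fixture
grid) bounds only the algorithmic error of the segmentation chain, not
observer-level CDR agreement.

## Problem sizes

Experiments are sized for a single CPU core: the default experiment uses 260
images (5% invalid) with an 80/20 stratified split and a 25% validation
carve-out for the threshold sweep, 18 training epochs; the desk-scale
learning check trains on 150 of 200 ROIs for 25 epochs; the cross-camera
experiment uses 120 style-A training images, 60 + 60 test images, and a
40-image fine-tuning set (25 + 8 epochs).

## Known limitations

- The intensity-based disc locator assumes the disc is the brightest large
  red structure; bright artifacts or flash reflexes would defeat it. The
  validity gate exists precisely to catch such failures downstream.
- No disc-size adjustment of CDR, no horizontal CDR, no nasal/temporal rim
  measurements.
- Platt calibration on few samples is coarse; SVM probabilities should be
  treated as rankings rather than frequencies at small n.
- The numpy conv net targets desk-scale experiments; it has no GPU path and
  no pretrained weights, and `vgg_like` at full resolution is slow.
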