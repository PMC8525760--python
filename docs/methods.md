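# Methods

## The classification problem

The pipeline automates Horse Grimace Scale (HGS) pain scoring from images.
The six HGS parameters are grouped into three facial regions — ears, eyes
(orbital tightening + tension above the eye), mouth-and-nostrils (chewing
muscles, mouth, nostrils) — and each region image is graded on the three
ordinal pain levels 0 (*not present*), 1 (*moderately present*),
2 (*obviously present*).  Region-level calls are then fused into one
whole-face pain level.  The pipeline stages and their contracts are
described module by module below, together with the design decisions that
were genuinely open and the choices made.

## Frame harvesting

The motion detector is the mean absolute pixel difference of consecutive
frames after grayscale conversion (ITU-R 601 luma for RGB input).  A frame
`i ≥ 1` is saved iff its score exceeds `motion_threshold`, more than
`min_gap` frames passed since the last save, and the optional `max_frames`
cap is not reached; frame 0 has no predecessor and is never saved.  The
operator choice was open — no specific algorithm is prescribed for the
original system — and the mean-absolute-difference rule was chosen as the
simplest operator that is exactly testable: the policy is a pure function
of the score sequence, so a hand simulation of the rule is an independent
oracle.  No downsampling is applied before scoring.

## Dataset and splits

A manifest CSV (columns `image_path, region, pain_level, animal_id,
source_frame, crop_x, crop_y, crop_w, crop_h, curated, split`) is the
single source of truth.  Crop boxes are 0-based, half-open, origin
top-left: the crop is `frame[y:y+h, x:x+w]`.  Rows sharing a
`source_frame` form one whole-face scene with a single pain level.
The manual frame-curation step of the original workflow is represented by
the boolean `curated` column; no automatic pose filter is implemented
because none is defined.

The reference database composition is 2379 ear, 1436 eye and 1035
mouth-and-nostril images (4850 total), heavily imbalanced for the ears
(1991/203/185 across the levels).  The train/validation/test split is
stratified per (region, class) cell: a cell of size `n` sends exactly
`floor(0.1·n)` rows to validation and to test, remainder to training.
This floor-per-class rule is the unique simple rule that reproduces all
nine reported per-region split sizes from the composition
(1905/237/237, 1152/142/142, 831/102/102); a plain 10% of the region
totals would give e.g. 143 ≠ 142 for the eyes.  A small epsilon
(`floor(f·n + 1e-9)`) guards against binary floating-point representation
of `0.1·n` landing just below an integer.

## Region CNNs

Architecture (identical across regions): conv 60 kernels 7×7 (ReLU) →
maxpool 2×2 → batch normalization → conv 32 kernels 5×5 (ReLU) → maxpool
2×2 → batch normalization → flatten → dense (ReLU) → dense 3 (softmax).
Per-region hyperparameters: input 200×200 / 80×80 / 120×120, penultimate
dense 1000 / 500 / 1000, epoch budget 20 / 30 / 30 for ears / eyes /
mouth-and-nostrils; batch size 50; three training replicates per region.
Convolutions are unpadded with stride 1, pools have stride 2 truncating an
odd trailing row/column; with these conventions the 80×80 eyes input flows
74 → 37 → 33 → 16, flattening to 8192 features.

Unstated details resolved here, exposed in the spec object and logged:

* **Optimizer** — RMSProp at 1e-3 (momentum-free adaptive).
* **Loss** — categorical cross-entropy on one-hot labels (softmax head).
* **Early stopping** — validation loss monitored every epoch, patience 5,
  hard cap at the epoch budget, best-epoch weights restored.  The original
  description says only that validation establishes a stop condition.
* **Replicate selection** — highest validation accuracy wins, ties to the
  lowest replicate index ("three trained models" per region is read as
  independent runs with one survivor).
* **Input handling** — grayscale by default (a `channels=3` flag exists),
  bilinear resize mapping output pixel center `i` to input coordinate
  `(i+0.5)·in/out − 0.5` with edge clamping, then scaling to [0, 1].
* **No data augmentation.**

The networks are implemented directly on numpy (im2col convolutions,
argmax-routed max pooling, per-channel batch normalization with running
statistics warm-started from the first batch so that short runs have
usable inference statistics).  Everything — initialisation, batch
shuffling, replicate seeds — derives from a single `numpy` SeedSequence,
so training is bit-reproducible.

The test suite and the synthetic benchmark use a scaled variant (32×32
input, 8/8 kernels, dense 32, 12 epochs, 2 replicates) so the whole suite
runs in well under a minute of CNN training; the full-size specs remain
the defaults for real runs.

## Fusion

Features are the nine confidences, ears → eyes → mouth-and-nostrils; the
discrete recommendations are omitted as redundant (recoverable by argmax
of the corresponding block).  The fusion net is a 9 → 5 (sigmoid) → 3
(linear) perceptron minimising MSE against one-hot targets by full-batch
gradient descent with learning rate 0.3 and momentum 0.2 — the reference
hyperparameters — for 500 epochs (configurable; the epoch count is not
stated anywhere).  The conflicting mention of Levenberg–Marquardt training
in the original description is not implemented: the printed learning-rate/
momentum pair implies the momentum-descent reading.

Evaluation is stratified 10-fold cross-validation with a seeded shuffle:
per-fold confusion matrices and accuracies are retained, the reported
accuracy is the fold average, a pooled out-of-fold confusion matrix is
kept for matrix reporting (whether the original fused matrix came from
pooled folds or a single split is unstated; pooling is the documented
choice), and a final model is refit on all records.  Predicted level is
the argmax of the three linear outputs, ties to the lowest index; the
linear head means the scores are not probabilities.

## Evaluation

Confusion matrices have reference (HGS) labels on rows and predictions on
columns.  Recall is the row-normalised diagonal, precision the
column-normalised diagonal, and overall accuracy trace/total — the
multiclass reading of the (TP+TN)/total formula, which reproduces every
printed corner value of the reference tables.  Undefined ratios (zero
row/column) are reported as NaN, never as 0.  Display values are rounded
half-up to one decimal (198/199 = 99.497 prints as 99.5) with full
precision retained internally.  The binary collapse keeps class 0 and
merges classes 1 and 2 by summing rows and columns; it conserves the grand
total and can only raise overall accuracy.

The five published evaluation matrices ship as CSV fixtures.  Note one
internal inconsistency of the source tables, reproduced deliberately:
collapsing the fused three-level matrix yields [[32, 8], [7, 73]] (87.5%)
while the published binary table is [[32, 8], [6, 74]] (88.3%) — a
one-sample discrepancy with no stated explanation.  Both the collapse
operator and the published binary fixture are provided; no reconciliation
is attempted.

## Synthetic data

The generator emulates the *structure* of the study data — three regions
per scene, three ordinal levels, per-animal captures at four daily
timepoints over six days, fixed-camera video with sparse motion — not its
appearance.  Images are 8-bit grayscale (optional RGB replication): a
low-frequency background texture (a seeded 4×4 grid bilinearly upsampled
to 170–230 gray) with dark ink strokes for facial features.

Pain level drives a latent intensity:

* raw latent `u ~ Uniform(class third)` — level 0 from [0, 1/3), level 1
  from [1/3, 2/3), level 2 from [2/3, 1) — the ordinal structure of the
  0/1/2 scale;
* separability `s ∈ [0, 1]` shrinks it to `l = 0.5 + s(u − 0.5)`; at
  `s = 0` every class renders from the identical latent 0.5, so the
  class-conditional image distributions coincide exactly and no classifier
  can beat 1/3 expected accuracy;
* the geometry parameter `g = (l + 0.25·⌊3l⌋)/1.5` is strictly monotone
  with jumps at the class boundaries, so at `s = 1` the classes occupy
  disjoint bands of `g` separated by gaps of ≈ 0.17.

`g` drives region geometry — ear-triangle spread (ears), orbital aperture
closing plus a fixed tension bar (eyes), nostril-ellipse dilation plus a
fixed lip line (mouth) — and the ink gray value `v(g) = round(30 + 80g)`.
The closed-form classification rule (the separability oracle) thresholds
the mean intensity of ink pixels (value < 140) at `v(g)` evaluated at the
inter-class gap midpoints g = 11/36 and 25/36.  Because `v` is affine
with ≥ 6 gray levels of margin at the gaps and rounding perturbs it by at
most half a level, the rule is exact — 100% on any noise-free,
separability-1 sample — which is what licenses the ≥ 95% accuracy
expectation placed on the CNNs under those conditions.  Additive Gaussian
pixel noise (`noise_sd`) and intermediate separability degrade the signal
continuously, giving a difficulty dial.

What the generator does **not** emulate: anatomy, pose, illumination,
occlusion, inter-animal variation, or any real covariance between regions
(all three regions share one latent).  Passing synthetic benchmarks
therefore demonstrates that the training/fusion machinery works — that
information present in the crops is extracted, fused and evaluated
correctly — not that the models would reach the published accuracies on
real horses.

Motion videos are a static textured background on which a quadrant block
(area ≈ magnitude/4 of the frame) flips between bright and dark at each
event frame, giving a guaranteed mean-absolute-difference floor of
`99 · block_area / frame_area` at events and exactly zero elsewhere at
zero noise.

## Problem sizes and numerical choices

The end-to-end synthetic benchmark trains on 80 scenes per class,
validates on 20 per class and evaluates fusion on 40 per class (120
scenes / 360 crops — the reference fusion-set size) at 96×96 scene
resolution with the scaled 32×32 CNNs; one full run takes roughly half a
minute on one CPU.  Ties in argmax (predictions, replicate selection,
pooling) always resolve to the lowest index.  Degenerate inputs are
rejected with named errors rather than coerced: empty videos, zero-sized
crops, off-simplex class weights, matrices that are not 3×3 where the
collapse is defined, fold counts exceeding the per-class record count.

## Known limitations

* The three region crops of a synthetic scene are perfectly correlated
  (one latent), so fusion cannot demonstrate a gain over the best single
  region on clean synthetic data — only non-inferiority.
* The published headline accuracies (90.3/65.5/74.5/75.8/88.3%) are
  reproduced from the published matrices, not re-measured on footage: the
  study's videos of the seven horses were never deposited.
* Full-size training (200×200, 60 kernels) is functional but slow on one
  CPU; the numpy implementation is optimised for the desk-scale specs the
  tests use.
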