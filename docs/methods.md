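# Methods

## Overview

`msknet` classifies knee MRI exams into binary injury categories
(abnormality, meniscus tear, bone marrow edema) from one to three MRI
sequences per exam. The pipeline has three stages:

1. **Feature-fusion preprocessing** — each series (a stack of `s`
   grayscale slices) is resized to `s x 224 x 224`, an intensity range of
   interest is applied (out-of-range pixels zeroed), pixels are
   z-normalized with statistics of the training split, and each slice is
   expanded into three channels: the normalized original, a local binary
   pattern (LBP) texture map, and the low-pass subband of a single-level
   Haar wavelet transform.
2. **KNet** — a convolutional backbone extracts per-slice features
   (`s x 256 x 7 x 7`), spatial average pooling yields `s x 256`, a
   learned linear score with a softmax over slices forms attention weights,
   and their weighted sum is a 256-dim exam embedding classified by a
   linear + logistic head at a fixed 0.5 threshold.
3. **MS-KNet** — one backbone+attention branch per input sequence (up to
   three); branch embeddings are fused by an arithmetic mean before a
   single shared classification head.

Training minimizes class-weighted binary cross-entropy
`L = -α y log(p) - (1-y) log(1-p)` with exam-at-a-time Adam; α defaults to
the negative/positive count ratio of the training split. Evaluation
reports accuracy, sensitivity (TP rate) and specificity (TN rate) at the
fixed 0.5 threshold.

## Preprocessing conventions

* **Windowing** happens before statistics fitting; zeroed pixels are
  included in the mean/sd, matching what the network sees. The default
  window is the full 16-bit range because clinically derived ranges are
  site-specific configuration, not shipped constants.
* **Normalization** uses the population sd over all windowed pixels of all
  training series. A zero-variance training set raises instead of
  dividing by zero.
* **LBP** is the classic 8-neighbor radius-1 code: bit *b* (MSB first,
  neighbors clockwise starting at the top-left) is set iff the neighbor is
  ≥ the center; borders use edge replication. Under the ≥ convention a
  constant image maps to code 255. LBP depends only on intensity order,
  so computing it before or after the affine z-normalization is
  equivalent; it is computed on the windowed, pre-normalization image.
* **DWT** is a single-level orthonormal 2-D Haar transform; the exported
  map is the LL (approximation) subband, upsampled bilinearly back to
  224 x 224 so it stays spatially registered with the other channels. The
  Haar LL of a constant image `c` is `2c`.
* **Channel harmonization**: the LBP and DWT channels are standardized to
  zero mean / unit sd per slice so all three channels are commensurate for
  the first convolution. A constant texture channel falls back to zeros
  (logged).

## Model

* **Backbones.** `tiny_cnn` (default for tests and experiments) is three
  strided conv/ReLU stages (3→16→64→256 channels, strides 8/2/2) mapping
  224 x 224 directly to 256 x 7 x 7; it is small enough to train from
  scratch on a CPU in minutes. `alexnet_random` is the stock five-conv
  AlexNet feature stack with adaptive average pooling from its native
  6 x 6 to the 7 x 7 contract; it is provided randomly initialized.
  `alexnet_pretrained` would require downloaded ImageNet weights, which
  the package does not bundle; constructing it raises. All backbones meet
  the same shape contract, so every model-level test is backbone-agnostic.
* **Slice aggregation.** The "weighted downsampling" is implemented as
  softmax attention: a linear map scores each slice's 256-vector, a
  softmax over slices turns scores into a probability vector, and the
  embedding is the weighted sum. This guarantees a convex,
  slice-permutation-invariant combination; with one slice it reduces to
  identity, and for identical slices it returns the common vector.
* **Head and threshold.** One linear unit plus logistic; a probability of
  exactly 0.5 resolves to the positive class (fixed convention).
* **MS-KNet fusion.** Branch backbones are independent (not weight-shared);
  fusion is the unweighted mean of branch embeddings, applied before the
  single shared head. A one-stream MS-KNet is numerically identical to
  KNet.
* The network, backpropagation and the Adam optimizer are implemented in
  numpy with explicit im2col convolutions; gradients are verified against
  central finite differences in the test suite.

## Training

* Batch size is one exam: slice counts vary from exam to exam, so the exam
  is the natural unit. Adam with learning rate 1e-3 trains the tiny
  backbone reliably within 20 epochs at desk scale (1e-4 under-trains it).
* Predicted probabilities are clamped to [1e-7, 1-1e-7] inside the loss so
  it stays finite; the clamp is invisible at reported precision.
* The training loop never touches test-split exams; passing a test exam id
  in the training list is a hard error, and preprocessing statistics are
  fitted on the training split only. Checkpoints carry a fingerprint of
  those statistics and evaluation refuses data preprocessed differently.
* No augmentation and no validation-based early stopping are used.

## Synthetic phantom

The generator emulates the *structure* of a multi-sequence knee MRI
cohort, not knee anatomy. Per exam:

* **Anatomy**: two bone-like ellipses separated by a joint-space band on a
  dark background (intensities 400 / 250 / 100, Gaussian-smoothed),
  extruded across `s ∈ [14, 56]` slices with a slow sinusoidal lateral
  drift and mild per-exam jitter. Jitter is deliberately small so the
  dominant between-exam variation is the lesion, which is what makes the
  cohort learnable by a small CNN trained from scratch.
* **Lesions** (amplitude = `lesion_contrast x noise_sd`, boundaries
  smoothed like the anatomy): meniscus tear → crescent-shaped hypointense
  discontinuity at the joint band; bone edema → diffuse hyperintense
  Gaussian blob inside a bone ellipse; "other" abnormality → hyperintense
  rim at the joint margin. Every lesion spans a contiguous run of at least
  three (in practice ≥60% of) slices.
* **Labels**: meniscus ~ Bernoulli(prevalence); edema conditioned on
  meniscus through a co-occurrence rate; the "other" lesion is planted in
  lesion-free exams with the probability needed to reach the configured
  overall abnormality prevalence. `abnormality = 1` iff any lesion is
  present, so manifest consistency holds by construction.
* **Sequences**: each configured sequence type is a deterministic contrast
  transform of the same lesioned anatomy (sagittal T1 = identity, axial T2
  = inverted window, coronal hybrid = mean of both, sagittal T2 = affine
  stretch) plus independent Gaussian noise. A `signal_sequences` knob
  renders lesions only into selected sequences, enabling attribution
  experiments where some streams are provably uninformative.
* **Defaults** mirror a realistic cohort: ~71% abnormal, ~31% meniscus,
  ~29% edema, edema in ~29% of torn-meniscus exams; slice counts 14–56;
  256 x 256 native pixels; noise sd 10; lesion contrast 10 (i.e. lesion
  amplitude 100 on a 100–400 anatomy scale — conspicuous, as real tears
  are to radiologists). Pixels are quantized to integers so the uint16
  DICOM round trip is lossless, and the whole cohort is a pure function of
  the seed.

What the phantom does **not** emulate: anatomical shape variation between
patients, MRI physics (bias fields, k-space artifacts, coil profiles),
inter-sequence geometric resampling, or graded/partial lesions. Passing
tests therefore demonstrate that the pipeline is implemented correctly and
can learn conspicuous planted signal — not clinical performance on
patient data.

* **Separability oracle**: a no-learning threshold classifier scores each
  exam by its mean hypointense deviation from a cohort-median reference
  image inside the union of lesion regions (anatomy edges excluded, where
  geometry jitter dominates). With `lesion_contrast ≥ 3`, it separates
  classes with ≥95% accuracy — the knob that guarantees planted signal is
  genuinely present.

## Experiments and problem sizes

The standing experiments (also run by `scripts/acceptance.py`) use
deliberately desk-scale sizes, chosen so the full suite runs in minutes on
one CPU:

* **Learnability**: 100 exams (60 train / 40 test), balanced meniscus
  prevalence, 14–18 slices at 128 x 128 native resolution, single
  sagittal-T1 stream, tiny backbone, 20 epochs at lr 1e-3. Expected: test
  accuracy ≥ 90%.
* **Signal attribution**: same scale, lesions rendered only into sagittal
  T1; a single-stream model trained on the blind axial-T2 stream is
  compared with a three-stream model that includes sagittal T1. Expected:
  the fused model is at least as accurate as the blind stream.
* **Ablation grid**: seven input combinations (four single sequences and
  three triples) x three tasks, one trained MS-KNet per cell, emitted as a
  seven-row matrix.

## Numerical choices

* Resize: bilinear, anti-aliasing on true downscales, same-size input
  short-circuits to an exact copy.
* Percentages: printed to one decimal with half-up rounding, computed in
  exact decimal arithmetic from the counts.
* Undefined metrics (no positives → sensitivity, no negatives →
  specificity) are reported as `None`/`NA`, never 0 or 100.
* Softmax scores are max-shifted before exponentiation; attention weights
  sum to 1 within 1e-6.
* All model math is float64; determinism is exact for fixed seeds.

## Known limitations

* The AlexNet backbone is available only with random initialization;
  transfer learning from ImageNet is out of reach offline.
* Exam-at-a-time optimization makes no use of inter-exam batching; wall
  time scales linearly with cohort size.
* The ablation harness retrains from scratch per cell; at clinical scale
  it should be parallelized or checkpoint-warm-started.
* Phantom realism is intentionally minimal (see above); conclusions about
  clinical data require clinical data.
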