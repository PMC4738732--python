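# Methods

## Problem and model

Given a fundus photograph, the package predicts a per-pixel saliency map of
where an ophthalmologist searching for diabetic macular edema (DME) would
look — a proxy for the diagnostically relevant regions of interest, which in
DME are bright exudate lesions near the fovea.  Writing `S = 1` for "pixel X
is in a region of interest" and `F_X` for the low-level feature vector at X,
and assuming position and appearance are independent,

    P(S | X, F_X)  ∝  P(S | X) · P(S | F_X)

The two factors are learned separately:

* **Feature Property** `P(S | F_X)`: a linear SVM over a 27-dimensional
  feature vector per pixel, trained on samples drawn from the extremes of
  expert fixation-density maps.  At test time the raw decision value
  `W·f + b` is used (not the sign): the ordering of pixels carries the
  salience information.
* **Position Property** `P(S | X)`: the pixelwise sum of the training
  images' fixation-density maps, min–max rescaled to [0, 1].  This captures
  the strong centre/fovea bias of DME diagnoses.

The final map is the Hadamard product of the two, smoothed with an isotropic
Gaussian of width δ = 10 px:

    M_s = (M_f ∘ M_p) ∗ GF(δ)

## Ground truth from gaze

Each observer views an image for 10 s; the first 1 s is treated as free
viewing and discarded.  Remaining fixations are accumulated on the pixel
grid and convolved with a unit-integral Gaussian (default σ = 2% of image
width; the kernel is truncated at ±4σ and mass falling outside the image is
lost).  Per-observer maps are normalised to unit sum before being overlapped
— "overlapping" is ambiguous between raw and normalised summation, and unit
sums prevent prolific observers from dominating; a flag restores raw
summation.  The overlap is min–max rescaled to [0, 1] per image.

## The 27 feature channels

1. **Steerable-pyramid local energy, 13 channels.**  A non-subsampled
   frequency-domain steerable pyramid: raised-cosine radial windows give
   octave-spaced bandpass filters at 3 scales, multiplied by one-sided cos³
   angular windows at 0°/45°/90°/135°; local energy is the squared magnitude
   of the complex (analytic) subband.  The 13th channel is the energy of the
   lowpass residual (the composition of the odd channel is not pinned down
   by the architecture; lowpass is the default and is configurable).
   Because no subsampling is used, no upsampling step is needed and the
   decomposition is defined at any image size; a warning is issued below
   ~32 px where coarse subbands overlap heavily.
2. **Conspicuity maps, 3 channels.**  Intensity, colour and orientation
   maps in the classic centre–surround architecture: dyadic Gaussian
   pyramids, centres at levels 2–4, surrounds 3–4 levels coarser, feature
   maps combined with a peak-promoting normalisation `N(m) = m·(1−mean)²`.
   Colour uses the centre–surround *contrast* of the broadly tuned R−G and
   B−Y opponent channels rather than the textbook double-opponency sum; the
   latter responds maximally to uniform colour fields, which is useless on
   a fundus image that is globally red.  Orientation uses Gabor energy
   (frequency 0.25/px) on the intensity pyramid.
3. **Colour statistics, 11 channels.**  Raw R, G, B; the per-pixel
   probability of each channel value under its marginal 8-bin histogram;
   and five per-pixel joint RGB probabilities from 8×8×8 histograms of the
   image median-filtered at windows 3, 5, 11, 21, 41 px.  Median filtering
   at growing scales makes rare colours (exudate yellow on a red field)
   stand out at matching lesion sizes.  Five scales are used so the stack
   totals exactly 27 channels.

Each channel is min–max normalised to [0, 1] (raw mode available for the
pyramid group) so the groups are commensurate; per-sample standardisation
(zero mean, unit variance, parameters estimated on the training set only)
happens inside the training step.

## Training the Feature Property

Per training image, positives are drawn uniformly without replacement from
pixels at or above the 80th percentile of the ground truth, negatives at or
below the 50th percentile; the strip between the strata is never sampled,
nor is anything within 10 px of an image border.  Default 100 samples per
image at a 1:1 ratio, pooled across training images.  The SVM is an
L2-regularised hinge-loss linear classifier at cost c = 1, solved in the
dual (liblinear family) with tol 1e-4 and a pinned random state.  Raising c
to 10⁴ changes held-out AUC by < 0.01 — but only once the solver is run to
convergence (tol 1e-6); with loose tolerance the large-c fit is
unconverged.  A 5:1 negative:positive imbalance costs ~0.03 AUC at the
few-hundred-sample scale of the test fixtures; ratios 1–2 are
indistinguishable.

## Combination

The decision map can be negative, and the product in `M_s` is only
meaningful for nonnegative salience, so `M_f` is min–max rescaled to [0, 1]
before the product (default; a raw mode is kept for ablation).  The
Gaussian is truncated at ±4δ with reflective boundary padding.  δ = 10 px
is wide relative to a single exudate, so the saliency peak typically sits
near the centroid of the lesion cluster rather than on one lesion — this is
a property of the method, visible in the tests.

## Evaluation

* **AUC** — the saliency map as a continuous classifier of ground-truth
  positive pixels, computed by the rank statistic with midrank ties.  The
  continuous ground truth is binarised at its top 20% (matching the
  positive-sample stratum); the fraction is configurable.
* **EMD** — exact optimal transport between the two maps as unit-mass
  distributions, with Euclidean ground distance, solved as a sparse linear
  program (HiGHS).  Maps are block-summed to a 16×16 grid first: exact
  transport on full-resolution images (or even 32×32 grids, ~60 s per pair)
  is computationally prohibitive.  Absolute EMD values are therefore
  comparable only within one grid configuration; cells holding < 1e-8 of
  the mass are dropped for solver stability (cost perturbation ≪ 1e-6).
* **SS** — sum of pixelwise minima of the unit-sum maps.
* **Sensitivity / specificity / Youden's J** — the map binarised at a
  salient-region fraction (default 50%) against the binarised ground truth;
  J = sensitivity + specificity − 1.  Binarisation marks exactly
  ⌈f·HW/100⌉ pixels, resolving ties in raster order.

Cross-validation partitions images into k = 10 seeded folds (sizes within
1); each fold's SVM *and* prior are fit on the training folds only, so no
test ground truth leaks into either factor.  Per-image metrics are averaged
(not pixel-pooled).  The "repeated 10-fold" protocol is independent seeded
repetitions.

## Synthetic data

The original expert eye-tracking corpus is not public, so the package ships
a generator whose defaults define the test conditions:

* **Images** (default 384×500, a 1/3-scale stand-in for 1152×1500): dark
  circular retinal field with vignetting and low-frequency mottle, a bright
  optic disc offset from the fovea, a recursive random-walk vessel tree, a
  darker macula, and 2–6 bright yellow exudate lesions whose centres lie
  within 40 px of the fovea.  Across a dataset the fovea is jittered by up
  to ±18% of each dimension, as fundus framing varies between
  acquisitions.  Pixel-unit parameters of the pipeline (10 px margin,
  δ = 10) are *not* rescaled with image size; they are specified in pixels
  of the processed image.
* **Gaze** (10 observers, 30 samples/s for 10 s): the first second is
  diffuse free viewing; later samples are lesion-targeted with probability
  0.8 (a uniformly chosen lesion pixel plus 4 px Gaussian jitter) and
  centre-biased otherwise (Gaussian, σ = 45 px around the fovea).  The 0.8
  weight reflects task-driven expert search — fixations land on lesions
  once orientation is over; with substantially lower weights the shared
  central cloud dominates every ground truth and the position prior alone
  explains all measurable performance, which contradicts the premise that
  the feature pathway carries image-specific information.

What the generator does **not** emulate: real lesion photometry and
texture, other lesion types (haemorrhages, drusen) that create hard
negatives, saccade dynamics and fixation durations, tracker noise and
calibration drift, and inter-observer disagreement structure.  Passing the
synthetic benchmark therefore shows the pipeline is internally consistent
and can recover a planted appearance-plus-position signal; it does not
certify clinical performance.

A consequence of realistic rendering worth noting: appearance encodes
position (the macula is darker, vessels thin toward the periphery), so a
feature model trained on mismatched ground truths degrades but does not
collapse to chance.  The shuffled-ground-truth control in the tests
therefore asserts a measurable degradation of the feature pathway, not a
collapse.

## Problem sizes in the test suite

Unit tests run on 128×168 images (10-image dataset, features cached per
session).  The recovery benchmark uses 30 images at the default 384×500
with 10-fold cross-validation, and the ablation control (full model >
prior-only > random, 5 seeds) uses 12 images at full scale with 4 folds.
On one CPU the whole suite runs in a few minutes; feature extraction
(~2 s/image) dominates.

## Known limitations

* Absolute EMD values depend on the transport grid; only within-run
  comparisons are meaningful.
* The steerable pyramid is non-subsampled; energies differ from a
  subsampled pyramid's upsampled energies by interpolation effects,
  although orientation/scale selectivity is equivalent.
* The conspicuity normalisation uses the simplified `(1−mean)²` operator,
  not iterative lateral inhibition.
* With δ = 10 and small lesions the saliency peak localises the lesion
  cluster, not individual exudates; detection of individual lesions would
  need a smaller δ or a deblurring step.
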