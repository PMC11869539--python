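# Methods

This note documents the models and procedures implemented in `imlts`, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about behaviour on real CT data.

## Synthetic phantoms

Each phantom is a float, HU-like intensity grid: a body background
(default 50), a darker elliptical "lung field" (default −800, semi-axes 42%
of the image extent), and one or more bright ellipsoidal nodules (default
40) of known physical diameter, with i.i.d. Gaussian noise (default
σ = 20, a moderate low-dose-CT-like level) added **after** the ground-truth
mask is rasterized. A voxel belongs to a nodule iff its center lies inside
the ellipsoid — an unambiguous rule whose rasterized area converges to the
analytic measure as resolution grows. Dataset sampling draws diameters
uniformly from 2–30 mm: the clinically annotated 3–30 mm range plus sub-3 mm
benign cases so both classes of the size rule occur. Default image geometry
is 128×128 at 0.5 mm/pixel. One integer seed drives a single
`numpy.random.default_rng` stream, making every phantom and split
bit-reproducible.

What the phantoms deliberately lack: reconstruction kernels, beam hardening,
spatially correlated noise, vascular/parenchymal texture, juxtapleural
nodules, and non-ellipsoidal shapes. Passing tests therefore demonstrate
correctness of the algorithms and of the pipeline plumbing, not clinical
performance; numbers measured here do not transfer to LIDC-IDRI/LISS-like
collections.

## Denoising

The denoiser is classical BayesShrink on a one-or-more-level separable
orthogonal DWT (default `db2`, one level, symmetric padding):

* noise scale: σ_N = median(|finest diagonal band|)/0.6745 (the MAD rule,
  exact for Gaussian noise); with multiple levels the finest-level estimate
  is reused, since white noise has the same scale in every orthogonal band;
* per detail band: σ_b² is the empirical second moment, the signal scale is
  σ_s = √max(σ_b² − σ_N², 0), and the threshold is T = σ_N²/σ_s, soft
  shrinkage by default. A band with σ_s = 0 carries no signal and is zeroed
  (the T → ∞ limit). The approximation band is never thresholded.

Two printed variants of the rule are exposed as opt-in knobs and are
identity by default: a cubic polynomial gain γ(δ) = g₁δ³+g₂δ²+g₃δ+g₄ on the
threshold (defaults (0,0,0,1), i.e. γ = 1; no published coefficient values
exist, so the neutral element is the only defensible default) and a
universal √(2 log N²) factor (off; with it on, thresholds are far more
aggressive than the Bayesian rule justifies, which the
`universal factor shrinks more` test demonstrates). Z-score normalization
(zero mean, unit variance; constant images are an error) is provided as the
pre-processing step and used for network input standardization.

Numerical notes: the inverse transform crops the one-sample padding that
odd-length axes incur, so round trips are exact to ~1e-12; soft thresholding
is elementwise a contraction, which the property tests assert.

## Radiomic features

Fifteen features per nodule ROI, computed on the largest axial slice for 3-D
inputs (the convention the size measurements also use).

**GLCM (4).** Intensities inside the mask are uniformly binned over the
ROI's min–max range into n levels (default 8 — the common radiomics default;
the source text leaves quantization unspecified). Pairs are counted only
when both voxels are in-mask, accumulated over the offset set (default the
four standard distance-1 2-D directions, symmetric), normalized to sum 1.
Contrast, correlation, homogeneity and entropy use the standard sums; note
the natural logarithm in entropy and the convention 0·log 0 = 0. A constant
ROI has a single diagonal GLCM entry, so correlation is undefined there
(zero marginal variance); `extract_features` reports 0 in that case.

**Shape (5).** Area = pixel count × pixel area. Aspect rate = major/minor
axis of the moment-matched ellipse (via `skimage.regionprops`, spacing
aware), clamped to ≥ 1. The perimeter is the length of the ordered outer
boundary polygon of the largest 8-connected component: the 0.5-level
marching-squares contour, simplified by Ramer–Douglas–Peucker to 1 px
tolerance before measuring, because the raw staircase polygon overestimates
digitized boundary length by ~7% for a disk (measured), which would push the
isoperimetric ratio of a perfect circle below 0.9. Roundness and circularity
are both 4πA/L² with L that perimeter — the source formulas differ only in
an undefined symbol, and the dimensionally consistent reading makes them
coincide; both are still reported.

**Histogram (6).** ROI intensities are binned into l = 256 uniform levels;
P_i is the bin-center intensity and HS(P_i) the normalized histogram. Mean,
variance, and *raw* third/fourth central moments (skewness, kurtosis —
deliberately not σ-normalized, matching the defining sums;
`normalized_moments=True` gives the conventional variants). Smoothness
1 − 1/(1+σ²) uses σ on the [0,1]-rescaled intensity axis so the value is
contrast-range invariant. Bin-center quantization means a two-point ±1
distribution yields variance (1−1/l)² ≈ 0.992, not exactly 1.

## Segmentation network

A U-NET with a mobile-style encoder, implemented directly on NumPy arrays
(NCHW) with hand-written forward/backward passes, validated by central
finite-difference gradient checks (layers agree to ~1e-9; whole-model checks
agree except at parameters sitting exactly on a ReLU kink, where central
differences are themselves invalid).

Architecture (desk-scale defaults, width multiplier 0.35, ~30k parameters):
a full-resolution 3×3 conv stage; a stride-2 stem; three stages of inverted
residual blocks (1×1 expand ×6 → 3×3 depthwise stride-s → 1×1 linear
project, shortcut add when shape-preserving) giving four 2× down-samplings
in total; a decoder of nearest-neighbour 2× up-sampling + 3×3 conv, each
level concatenating the encoder feature map of equal resolution; a 1×1
sigmoid head. Instance normalization (per sample, per channel, learned
affine) follows every convolution: it plays the role batch normalization has
in the reference mobile design but is independent of batch composition, so
prediction is deterministic and identical for any batching. The
full-resolution stage exists because 2–4 voxel nodules are otherwise lost by
the immediate stride-2 stem.

Training: Dice loss 1 − (2Σpt+ε)/(Σp+Σt+ε), ε = 1e-6, averaged per sample;
Adam (β 0.9/0.999); seeded shuffling and seeded horizontal/vertical flip
augmentation (nodules have no preferred orientation). The validation-plateau
rule multiplies the learning rate by 0.01 after 4 consecutive epochs without
improvement (the plateau counter then resets); training stops after 10
epochs without improvement and the best-validation weights are restored.
The learning rate never increases.

Presets: the full-scale configuration (256×256 patches, batch 8, Adam 1e-4,
90 epochs) is the `NetworkConfig` default; tests and the pilot use
`NetworkConfig.desk_scale()` — 64×64 patches, batch 8, Adam **1e-2**, 15
epochs. The higher rate is deliberate: instance-normalized small CNNs train
stably in that regime, and at 1e-4 the 15-epoch pilot budget is nowhere near
convergence. Patches are sampled half nodule-centered (with jitter), half
uniform background, countering the empty-mask class imbalance; each source
image is Z-score standardized *as a whole* before cropping, so background
crops stay flat instead of having their noise amplified to unit variance.

Prediction tiles arbitrary image sizes with half-patch overlap averaging and
processes 3-D volumes slice-wise. Checkpoints are single `.npz` files with a
versioned JSON header.

The pilot regression baseline (20 phantoms, 200 patches, ≤15 epochs, one
CPU, ~80 s) reaches mean thresholded validation Dice 0.85–0.95 across seeds.

## Classification

Equivalent diameter d = 2√(A/π) from the largest axial slice of each
connected component (8-/26-connectivity), components ordered by area. The
size rule calls d ≥ 3.0 mm malignant — inclusive at the boundary. The SVM
backend standardizes the 15 features and fits `sklearn` SVC with
gamma = 1/s², exactly matching the hand-written kernel
R(a,b) = exp(−‖a−b‖²/s²); note the s² (not 2s²) denominator, kept as
defined, with `standard_form=True` switching to 2s². C defaults to 1.0
(conventional; unspecified in the source). The pipeline's
`svm_with_rule_fallback` backend uses the SVM when both classes were
available for training and the size rule otherwise, making the two stated
mechanisms' interaction explicit.

## Evaluation

Rates in percent with malignant as the positive class: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), accuracy
(TP+TN)/N, F-score the harmonic mean of precision and sensitivity, error
rate 100 − accuracy. Undefined rates (zero denominator) are NaN markers,
never exceptions. Two printed-formula defects were corrected to the only
internally consistent forms: a specificity numerator (TP → TN) and a
variance subtrahend in the denoiser (see above); both are noted at the
definitions in code.

## Pipeline and reproducibility

`run_pipeline` executes synth → denoise → train → segment → features →
classify → evaluate with dependency checking, writing every artifact under
the run directory and a manifest with SHA-256 checksums. All stochastic
stages derive from the single config seed; two runs with the same config are
byte-identical except wall-clock timestamps (stored outside the checksummed
stage records). Problem sizes used by the test suite and the acceptance
script — 10–20 phantoms, 24–200 patches, 2–15 epochs — were chosen as the
smallest sizes at which each property is stably measurable.

## Known limitations

* Phantom realism as above; no claims transfer to real CT.
* The NumPy network is single-threaded-BLAS CPU code; the full-scale
  256×256/90-epoch preset, while expressible, is impractical without a
  GPU runtime.
* 3-D inputs are segmented slice-wise and measured on axial slices; no true
  volumetric network.
* GLCM and histogram features use the largest axial slice of 3-D ROIs, not
  full-volume statistics.
* The SVM trains on ground-truth-mask features of the synthetic train split;
  on phantoms its decision is dominated by the size-correlated features, so
  its agreement with the size rule is high by construction.
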