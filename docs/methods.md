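# Methods

## Model

The classifier is a hybrid of three fixed-random-feature networks (one per
RGB channel) and a trained fusion head. Per channel:

    input (H×W, [0,1])
      → morphological layer: 4 parallel ops, each with its own binarized 5×5 SE
      → max-pool 2×2 → ReLU
      → convolution: 5 kernels 5×5×4, stride 1, zero same-padding, no bias
      → max-pool 2×2 → ReLU
      → flatten (row, column, map) → linear output unit (the only trained part)

The morphological layer computes, on the same input, erosion, dilation,
opening, and the residual (input − erosion). Operators are *flat*: erosion
is the moving minimum over the active cells of a binary structuring
element (SE), dilation the moving maximum over the reflected SE. Same
padding uses the reduction's neutral element (1.0 for min, 0.0 for max) so
borders never introduce spurious extrema in [0, 1] images. Closing and
residuals of other operations are implemented and exported but are not
part of the default layer, which uses the four operations listed above;
each operation owns its own filter, including the residual (its internal
erosion uses the fourth filter, not the erosion map's).

SE binarization: each real 5×5 filter is min–max normalized and
thresholded at 0.5 (the midpoint of the normalization range). A constant
filter has no range; it degenerates to the center-only SE, making the
operation the identity. Consequently every SE has at least one active
cell, and (for non-constant filters) at least one inactive cell: the
maximum always binarizes to 1 and the minimum to 0.

Interpretation note: with binary weights a literal product `x_i · w_i`
inside the min/max would zero every erosion wherever `w_i = 0`; the masked
min/max over active cells is the only reading under which the operators
behave as erosion/dilation, and is the standard definition of flat
grayscale morphology.

## Training

All hidden filters are He-initialized (`N(0, 2/fan_in)`) from the
network's seed and never updated. The single output unit per channel is
solved as a ridge regression on ±1 targets (an extreme learning machine).
The solver uses the primal normal equations when N ≥ d and the
algebraically identical dual form when N < d; with d = 20,481 and a few
hundred images the dual form is the operative path and only ever
factorizes an N×N matrix. λ (default 1.0) is the model's single training
hyperparameter; it is exposed everywhere a fit happens.

Scores are mapped to probabilities by the logistic function. Any strictly
increasing map would serve the downstream head equally; logistic is the
conventional choice. The head (Random Forest, 500 trees, fixed seed by
default) is fit on the (N, 3) matrix of per-channel training
probabilities. Alternative heads (Gaussian Naive Bayes, SVM with
probability outputs, AdaBoost) use library defaults — they are comparison
baselines, not tuned models — and swapping heads never refits the channel
networks.

Architecture constants fixed by the parameter-count argument: pooling is
2×2 with stride 2 after each of the two layers, and each channel network
has a single output unit. These are the choices under which the full model
trains 3 × ((256/4)² · 5 + 1) = 61,443 ≈ 6.1 × 10⁴ parameters. Pool-first
vs ReLU-first is immaterial (they commute for max-pooling); pooling first
is cheaper. Hidden layers carry no biases, which keeps the all-zero-input
→ all-zero-features property exact.

## Synthetic data

The generator emulates the two geometric disease signatures the model
targets, with the class signal carried by geometry only:

- `disc_cup` — bright disc (intensity 0.65) of radius ~0.30·S (S = image
  side, SD 0.02·S) on a dark background (0.20), with an inner brighter cup
  (0.90). The cup/disc radius ratio is `N(0.40, 0.06)` for negatives and
  `N(0.40 + e·0.06, 0.06)` for positives, where `e` is the effect size in
  pooled-SD units.
- `lesion_border` — dark blob (0.30) on light background (0.75) whose
  polar radius is perturbed by harmonics 3–8 with random phases; the
  total harmonic amplitude (border roughness) is `N(0.04, 0.015)` for
  negatives, shifted by `e·0.015` for positives.

Center position, base radius, cup/disc intensities and per-channel tint
jitter (multiplicative, SD 0.05 around a red-dominant fundus-like weighting)
are all class-independent. Each grayscale pattern is shifted to a fixed
mean brightness (0.45) before tinting, so mean intensity carries no class
information — verified by the chance-level AUC of a mean-intensity
classifier. Additive Gaussian noise (default SD 0.05) is applied last and
intensities are clipped to [0, 1]; clipping can reintroduce tiny
class-independent intensity shifts, which the no-leakage test tolerates.
At `e = 0` the class-conditional distributions are identical by
construction. Generation is a pure function of the config (bitwise
reproducible).

Defaults (200 images per class, 256×256, effect size 3, noise SD 0.05)
define the standard synthetic task used by the end-to-end tests. What
passing on this task shows: the pipeline can recover a purely geometric,
morphology-sized class difference from realistic-count samples. What it
does not show: performance on real fundus/dermoscopy images, which carry
texture, vasculature, illumination fields and annotation noise the
generator deliberately omits.

## Evaluation protocol

Metrics: accuracy, balanced accuracy (mean of sensitivity and
specificity), AUC (midrank tie handling), error = 1 − accuracy, at
threshold 0.5 on head probabilities. Confidence intervals are 95%
percentile bootstrap over B = 2,000 stratified resamples of the test set
(resampling within each class keeps every resample two-class); the
bootstrap is the package's uniform CI method for all four metrics.

Experiments, all driven by one master seed from which every split/model
seed is derived (so reruns are bitwise identical, and raw per-run rows are
stored alongside every summary):

- *Seed stability*: one stratified 80/20 split held fixed; the model is
  refit under 10 seeds (filter initialization and head randomness vary
  jointly); mean/variance/SD/median per metric are reported.
- *Split robustness*: 30 distinct stratified 80/20 splits; medians are the
  headline.
- *Channel ablation*: per split, each single-channel network's
  0.5-thresholded accuracy against the full fused model.
- *Head comparison*: channel networks fitted once per split; every head
  fitted on the same probability matrix (its SHA-256 hash is recorded per
  row so the identical-input contract is auditable from the report).

## Numerical choices

- The network forward pass runs in float32 internally (min/max, pooling
  and ReLU are exact in any float width; the convolution contraction is
  well inside tolerance); the ELM solve upcasts to float64. Features for a
  400-image set extract in a few seconds per channel on one core.
- Ridge solves use Cholesky (`assume_a="pos"`); λ > 0 is required — the
  λ = 0 system is singular in the N < d regime.
- Stratified splits shuffle within class and cut at rounded cumulative
  fractions, guaranteeing per-part class proportions within one sample.
- Resizing is bilinear (Pillow), pinned because interpolation affects
  pixel values; intensity normalization is a global /255 (no per-image
  standardization), matching the morphology layer's [0, 1] contract.

## Problem sizes in the test suite

The end-to-end acceptance tests run the default synthetic task (200/class,
256×256): one ten-seed fixed-split experiment serves both the recovery and
stability checks, single fits at effect sizes 0 and 1.5 support the
monotonicity check, and the ablation uses five splits. Unit and property
tests use 8×8–64×64 images where the property under test is
size-independent. Bitwise-reproducibility is asserted at 32×32 with 3
seeds.

## Known limitations

- Single morphological layer and fixed operation set; no gradient-based
  learning of structuring elements (the ELM reading: hidden weights stay
  at initialization).
- Binary classification only; one probability per channel feeds the head.
- The bootstrap CI is a stand-in where no interval construction is
  otherwise specified; it is assumption-free but can be wide at small n.
- The synthetic tasks are deliberately minimal geometric surrogates, not
  photorealistic simulations.
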