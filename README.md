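# mcnn — hybrid morphological-convolutional networks for small image datasets

`mcnn` implements a compact binary image classifier aimed at medical
diagnosis problems where only a few hundred labeled images exist — too few
to train a deep CNN without overfitting — and where the diagnostic signal
is *geometric*: the cup-to-disc ratio of an optic nerve head in fundus
photographs, or the border irregularity of a skin lesion in dermoscopy.

## The model

Each RGB channel is processed by its own shallow two-layer network:

1. **Morphological layer.** Four flat grayscale operations are applied in
   parallel to the same input `X`: erosion `X ⊖ w`, dilation `X ⊕ w`,
   opening `(X ⊖ w) ⊕ w`, and the residual `X − (X ⊖ w)`. Each operation
   has its own 5×5 structuring element `w`, obtained by min–max normalizing
   a He-initialized real filter and thresholding at the midpoint 0.5.
   Erosion/dilation are the moving min/max over the active cells of `w`
   (stride 1, same padding with the reduction's neutral element).
2. **Convolutional layer.** Five 5×5 kernels over the four morphological
   maps (stride 1, zero same-padding, no bias). Both layers are followed by
   2×2 max-pooling and a ReLU.

The hidden filters are random and **fixed**; only the single linear output
unit per channel is trained, in closed form, as an extreme learning
machine (ELM) ridge solve with targets `t ∈ {−1, +1}`:

    β = (HᵀH + λI)⁻¹ Hᵀt        (N ≥ d)
    β = Hᵀ(HHᵀ + λI)⁻¹ t        (N < d, the usual small-sample regime)

where `H` is the matrix of flattened features (bias column appended). At
the 256×256 working resolution each channel network has
(256/4)·(256/4)·5 = 20,480 features, so the full model trains
3 × 20,481 = **61,443** parameters (≈ 6.1 × 10⁴) — orders of magnitude
fewer than a compact CNN. The three per-channel logistic probabilities
`σ(h·β)` are finally fused by a Random-Forest head (Gaussian Naive Bayes,
SVM and AdaBoost are available as comparison heads).

Because no external medical images ship with the package, a seeded
synthetic generator (`mcnn.synthetic_data`) produces two-class image sets
whose class signal is purely geometric — disc/cup size ratios or
Fourier-perturbed lesion borders — at a configurable effect size, so the
whole pipeline is exercisable end to end offline.

## Worked example

```python
from mcnn import MCNNModel, SyntheticConfig, generate, count_parameters
from mcnn.dataset_io import stratified_split
from mcnn.evaluation import evaluate_scores

config = SyntheticConfig(mode="disc_cup", n_per_class=60, image_size=(64, 64),
                         effect_size=3.0, seed=7)
images, labels, manifest = generate(config)
split = stratified_split(labels, seed=0)          # stratified 80/20
model = MCNNModel(input_size=(64, 64), seed=1)
model.fit(images[split.train], labels[split.train])
metrics = evaluate_scores(labels[split.test], model.predict_proba(images[split.test]),
                          ci=True, seed=0)
for name in ("accuracy", "balanced_accuracy", "auc", "error"):
    lo, hi = metrics.ci[name]
    print(f"{name:18s} {getattr(metrics, name):.3f}  (95% CI {lo:.3f}, {hi:.3f})")
```

prints

```
accuracy           0.833  (95% CI 0.667, 0.958)
balanced_accuracy  0.833  (95% CI 0.667, 0.958)
auc                0.903  (95% CI 0.747, 1.000)
error              0.167  (95% CI 0.042, 0.333)
```

On 120 images (96 train / 24 test) whose classes differ only in the
cup-to-disc ratio (three pooled SDs apart), the fused model reaches test
AUC 0.90: a random positive image outscores a random negative one 90% of
the time. The CIs are percentile bootstrap intervals over 2,000 stratified
resamples of the 24-image test set — wide, as expected at this n.
`count_parameters("full-mcnn")` reports the 61,443 trained parameters of
the default 256×256 configuration.

The same workflow is available from a shell:

```sh
mcnn simulate --mode disc_cup --n-per-class 200 --effect-size 3 --seed 0 --out data/
mcnn train --manifest data/manifest.csv --seed 1 --out-model model/
mcnn evaluate --model model/ --manifest data/manifest.csv --report report.csv
mcnn experiment --kind stability --manifest data/manifest.csv --out exp/
```

Evaluation experiments (`mcnn.evaluation`) mirror the model's standard
protocol: a 10-seed stability study on a fixed stratified 80/20 split,
medians over 30 independent splits, a per-channel ablation, and a
fusion-head comparison in which all heads consume bit-identical
per-channel probabilities.

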