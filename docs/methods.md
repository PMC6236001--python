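# Methods

## Problem and model

The task is binary classification of 2-D grayscale axial brain slices:
multiple sclerosis (MS, the positive class) versus healthy control (HC).
The discriminating feature is the presence of small hyperintense
white-matter plaques. The classifier is a convolutional network of 11 conv
layers and 3 fully-connected layers (pooling, batch normalization, dropout
and softmax are uncounted sublayers, hence "14-layer"). All conv kernels
are 3×3 with "same" zero padding; strides and channel widths follow the
fixed table encoded in `model.default_config()` and shipped as
`arch/msnet14.yaml`.

The input resolution 256×256×1 is a derived quantity, not a free choice:
the first FC layer consumes a 1024-unit vector, which equals 64 channels ×
4 × 4, and the layer chain contains exactly six stride-2 stages under
"same" padding (output side = ⌈input/stride⌉), so the input side must be
4 · 2⁶ = 256. `model.shape_trace` performs this propagation for any config
and is the single source of truth for flatten dimensions; `model.build`
derives FC weight shapes from it rather than hard-coding them.

## Layer mathematics

* **Convolution** is cross-correlation with stride M; for explicit padding
  N the output side is 1 + ⌊(2N + H − H_F)/M⌋, for "same" padding
  ⌈H/M⌉ with the total padding split evenly (extra pixel trailing).
* **Batch normalization** standardizes each channel with the biased (1/m)
  mini-batch moments, then applies the learnable affine (γ, β). ε = 1e-5
  (the conventional framework default; the alternative reading exp(−5) of
  the stated constant was rejected as nonstandard). Running moments for
  inference are exponential moving averages with momentum 0.1
  (configurable). Batch norm attaches to conv layers only.
* **Dropout** is inverted: units are zeroed with p = 0.5 and survivors
  scaled by 1/(1−p) at train time, so inference is the identity.
* **Pooling** is 3×3, stride 2, "same" padding. Padded positions are
  excluded from average denominators and carry no probability mass in
  stochastic pooling (zero-valued after ReLU). Max/average are standard.
* **Stochastic pooling** assumes non-negative (post-ReLU) inputs. Training
  samples location l with P(l) = χ_l/Σχ (an all-zero region outputs 0,
  with uniform probabilities as the degenerate convention) and the
  gradient is routed to the sampled location, exactly as max pooling
  routes to the argmax. Inference uses the expectation Σ p_i χ_i =
  Σχ²/Σχ, making every forward pass deterministic.
* The network is trained with mini-batch SGD + momentum 0.9 on softmax
  cross-entropy, with a step-decay schedule lr(e) = lr₀ · f^⌊e/period⌋
  (defaults lr₀ = 0.01, f = 0.1, period = 10). The optimizer itself is a
  design choice; only "start large, drop every fixed number of epochs" is
  prescribed.

The whole engine is pure numpy (im2col convolution, strided-view pooling
windows); backward passes are verified against central-difference
numerical gradients in the test suite. He-style initialization
(σ = √(2/fan_in)) is used because every nonlinearity is ReLU; the
initialization scheme is otherwise unconstrained.

## Augmentation

Five operators, applied to the training branch only. Rotation, rescaling
and gamma grids are inclusive ranges that would contain 31 values each;
the identity parameter (0°, s = 1, r = 1) is excluded so each contributes
30, which together with the two stated 30-draw stochastic operators gives
exactly 150 derivatives per original (151× training set). Translation
draws an integer magnitude uniform on [0, 15] and an independent uniform
sign per axis (only the magnitude range is prescribed; independent axes
and symmetric signs are this package's choice). Geometric transforms use
bilinear interpolation with zero fill — zeros match the dark MRI
background — and outputs are clipped/kept in [0, 1]; noise (variance 0.01)
is meaningful only on the normalized scale and is therefore added after
histogram stretching.

## The exact signed-rank test

Run tables are small (n = 10) and non-Gaussian, so pooling variants are
compared with the exact two-sided Wilcoxon signed-rank test. Conventions,
each pinned by reproducing the published comparison table to four
decimals: zero differences dropped before ranking; average ranks for tied
|d|; the null distribution taken conditional on the observed (tied) rank
vector; p = 2·P(W ≤ min(W+, W−)) capped at 1. `stats.exact_tail`
enumerates all 2^n sign assignments via a generating-function convolution
over the doubled ranks (ties make average ranks half-integers); a naive
2^n loop serves as the independent oracle in the tests. The enumeration is
capped at n = 30 pairs; no normal approximation is provided.

## Synthetic phantoms

`synthdata` generates what the pipeline needs and nothing more: a centered
ellipse of low-pass-filtered Gaussian texture over a dark background, with
MS slices carrying 1–4 hyperintense Gaussian blobs (radius ~1.5–3.5 % of
the image side) at uniform positions inside the ellipse. `plaque_contrast`
(default 0.35) is the separability knob; at 0 the class distributions
coincide exactly. The two classes pass through different "virtual
scanners" (affine intensity gain/offset), giving histogram stretching a
real inter-source matching job; observation noise is added *before* the
scanner transform so that per-image stretching cancels the scanner
difference exactly and no class signal leaks through the noise scale.
Default class sizes are 676 MS / 681 HC, matching the reference data's
slice counts.

What passing tests on phantoms do **not** show: performance on real MRI.
The phantoms have no anatomy, no partial-volume effects, no bias fields,
no inter-subject variability, and a single blob-shaped lesion model; the
published headline accuracies are not recomputable because the underlying
clinical data is not publicly accessible.

## Problem sizes used in the test suite

Tests run the method at reduced scale, chosen as the smallest sizes at
which each property is still meaningfully exercised: the training sanity
check uses 2,000 phantoms at 64×64 with the reduced (3 conv + 2 FC)
variant for 5 epochs; the augmentation ablation uses five paired
experiments of 240 phantoms at 32×32, three runs each, with a 20-per-image
augmentation grid; separability and null-calibration checks use 160
phantoms at 32×32. The full 256×256 architecture is exercised through its
shape arithmetic, parameter counts and forward-pass contracts rather than
full training runs.

## Known limitations

* Degenerate runs: a collapsed predictor that never calls MS has
  undefined precision; `multirun` records that cell as NaN instead of
  aborting (strict single-run metric computation still raises).
* The numpy engine targets clarity and CPU-scale experiments, not GPU
  throughput; training the full 256×256 architecture on a 105,700-image
  augmented set is possible but slow.
* Stochastic-pooling sampling uses one shared rng stream per training
  step; reproducibility is guaranteed only through the seeded TrainConfig
  path, not across numpy versions.
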