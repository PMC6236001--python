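# msnet

Identification of multiple sclerosis (MS) from healthy-control (HC) brain
MRI slices with a 14-layer convolutional neural network that combines batch
normalization, dropout and **stochastic pooling**, plus the statistical
harness needed to compare pooling variants rigorously.

The package is aimed at researchers studying small-sample medical-image
classification: it provides the full method as a tested library and CLI —
contrast normalization, a deterministic five-transform augmentation scheme,
the network itself (pure numpy, trainable on CPU), a repeated hold-out
evaluation harness, and an exact Wilcoxon signed-rank test — together with
a seeded synthetic phantom generator, so every stage can be exercised
end-to-end without access to clinical data.

## The method

**Contrast normalization.** Slices from different scanners are matched by
per-image histogram stretching: φ(x,y) = (μ(x,y) − μ_min)/(μ_max − μ_min),
mapping each image's own range onto [0, 1].

**Augmentation (training branch only).** Each training image generates 150
derivatives: 30 rotations (θ ∈ −30…30° step 2°), 30 rescalings
(s ∈ 0.7…1.3 step 0.02), 30 Gaussian-noise injections (zero mean, variance
0.01), 30 random translations (|t| ≤ 15 px per axis), and 30 gamma
corrections (r ∈ 0.4…1.6 step 0.04) — a 151× training set.

**The network.** 11 conv layers (3×3 kernels, "same" padding) and 3 FC
layers; every conv layer carries batch normalization and ReLU, the first
two FC layers carry dropout (p = 0.5). Six stride-2 stages reduce a
256×256×1 input to 4×4×64, flattened to the 1024-unit input of
FC(1024→20)→FC(20→10)→FC(10→2)→softmax.

**Stochastic pooling.** Within each 3×3 pooling region R_j, activation χ_i
is selected with probability p_i = χ_i / Σ_k χ_k. Training samples one
location per region (the gradient follows the sampled location); inference
uses the deterministic expectation Σ_i p_i χ_i. This keeps the
noise-robustness of average pooling without down-weighting strong
activations, and regularizes like max pooling without its overfitting.

**Evaluation.** Repeated hold-out: each of 10 runs re-draws the split
(350/350 train, 326/331 test in the reference setting), re-augments,
retrains from scratch and reports sensitivity, specificity, precision and
accuracy (MS positive); runs are summarized as mean ± sample SD.

**Pooling comparison.** Paired per-run metrics of two pooling variants are
compared with the Wilcoxon signed-rank test using its *exact* null
distribution: zero differences dropped, average ranks for ties, and
p = 2·P(W ≤ min(W+, W−)) by exhaustive enumeration of all 2^n sign
assignments conditional on the observed rank vector.

## Worked example

Train the reduced variant on synthetic phantoms (64×64, 600 slices,
stochastic pooling — small enough for a laptop CPU):

```python
from msnet import model, preprocess, synthdata
from msnet.preprocess import HC, MS, HoldoutSpec
from msnet.train_eval import TrainConfig, compute_metrics, evaluate, train

params = synthdata.SynthParams(image_side=64, plaque_contrast=0.35, seed=20)
dataset, _ = synthdata.generate_dataset(params, 300, 300, seed=20)
dataset = preprocess.normalize_dataset(dataset)
tr, te = preprocess.holdout_split(
    dataset, HoldoutSpec({MS: 200, HC: 200}, {MS: 100, HC: 100}, seed=21))
net = model.build(model.small_config(64, "stochastic"), init_seed=22)
net, losses = train(net, tr, TrainConfig(epochs=5, batch_size=32, seed=23))
print(compute_metrics(evaluate(net, te)))
```

This prints a per-epoch loss trace of `[0.515, 0.108, 0.033, 0.023, 0.014]`
and a perfect confusion matrix (TP=100, FP=0, TN=100, FN=0), i.e.
sensitivity/specificity/precision/accuracy all 100.00 — the phantoms at
this plaque contrast are cleanly separable once the net has converged.

The pooling comparison on the published ten-run benchmark tables:

```sh
$ msnet compare-pooling --metric accuracy
metric: accuracy
W- = 0.0, W+ = 55.0, n_effective = 10
exact two-sided p = 0.0020
```

Every accuracy difference favors stochastic over average pooling, so
W− = 0 and the exact two-sided p-value is 2/2¹⁰ ≈ 0.0020.

`msnet describe-arch` prints the full shape trace of the 14-layer network
(ending `pool_4 → 4×4×64`, `flatten dimension: 1024`, 143,396 trainable
parameters). Other subcommands: `simulate`, `preprocess`, `split`,
`augment`, `train`, `multirun`.

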