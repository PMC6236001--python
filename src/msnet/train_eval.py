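"""Training, hold-out evaluation and the multi-run experiment harness.

Training uses mini-batch SGD with momentum and cross-entropy loss on the
softmax outputs, with a step-decay learning-rate schedule: the rate starts
large and is multiplied by ``lr_drop_factor`` every ``lr_drop_period``
epochs.  Evaluation runs the network in inference mode (deterministic for
every pooling mode — stochastic pooling switches to its expectation) and
reports the standard confusion-matrix metrics with MS as the positive
class.  The multi-run harness repeats the whole experiment: each run
re-draws the hold-out split, optionally re-augments the training branch,
trains from a fresh initialization and evaluates; the run table is
summarized as mean +/- sample standard deviation per metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import errors
from .augment import AugmentConfig, augment_training_set
from .layers import softmax_cross_entropy
from .model import ArchitectureConfig, Network, build
from .preprocess import CLASSES, MS, HoldoutSpec, ImageDataset, holdout_split

METRIC_COLUMNS = ("sensitivity", "specificity", "precision", "accuracy")


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters with a step-decay learning-rate schedule."""

    initial_lr: float = 0.01
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    epochs: int = 30
    batch_size: int = 128
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch-norm requirement)")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with MS as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, precision, accuracy — all in percent."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sensitivity, self.specificity, self.precision, self.accuracy)


def round2(x: float) -> float:
    """Round half-up to two decimals (report-time only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Step-decay schedule: initial_lr * factor^floor(epoch / period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * config.lr_drop_factor ** (epoch // config.lr_drop_period)


def train(network: Network, train_set: ImageDataset,
          config: TrainConfig) -> tuple[Network, list[float]]:
    """Mini-batch SGD with momentum; returns the network and per-epoch mean loss.

    Dropout and batch norm run in train mode; stochastic pooling samples per
    forward pass.  Fully deterministic given ``config.seed``.
    """
    if len(train_set) == 0:
        raise errors.EmptyTrainingSet("training set is empty")
    counts = train_set.class_counts()
    if min(counts.values()) == 0:
        raise errors.SingleClassTrainingSet(f"both classes required, got {counts}")
    X, y = train_set.to_arrays()
    rng = np.random.default_rng(config.seed)
    velocity = [np.zeros_like(p) for p, _ in network.params()]
    losses: list[float] = []
    n = len(train_set)
    for epoch in range(config.epochs):
        lr = lr_at(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            logits = network.forward_logits(X[idx], mode="train", rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            network.backward(dlogits)
            for v, (p, g) in zip(velocity, network.params()):
                v *= config.momentum
                v -= lr * g
                p += v
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return network, losses


def evaluate(network: Network, test_set: ImageDataset,
             batch_size: int = 128) -> ConfusionMatrix:
    """Inference-mode predictions (argmax probability) tallied against labels."""
    if len(test_set) == 0:
        raise errors.EmptyTestSet("test set is empty")
    X, y = test_set.to_arrays()
    preds = np.empty(len(y), dtype=np.int64)
    for start in range(0, len(y), batch_size):
        logits = network.forward_logits(X[start : start + batch_size], mode="inference")
        preds[start : start + logits.shape[0]] = logits.argmax(axis=1)
    pos = CLASSES.index(MS)
    tp = int(((preds == pos) & (y == pos)).sum())
    fn = int(((preds != pos) & (y == pos)).sum())
    tn = int(((preds != pos) & (y != pos)).sum())
    fp = int(((preds == pos) & (y != pos)).sum())
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(cm: ConfusionMatrix, strict: bool = True) -> Metrics:
    """Standard confusion-matrix rates in percent (full precision, unrounded).

    With ``strict=True`` (the default) a zero denominator raises
    :class:`~msnet.errors.UndefinedMetric`.  The multi-run harness instead
    uses ``strict=False``, which records the undefined metric as NaN so one
    degenerate run (e.g. a collapsed predictor with no positive calls)
    does not abort a whole experiment.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0 or (strict and cm.tp + cm.fp == 0):
        raise errors.UndefinedMetric(f"zero denominator in {cm}")
    return Metrics(
        sensitivity=100.0 * cm.tp / (cm.tp + cm.fn),
        specificity=100.0 * cm.tn / (cm.tn + cm.fp),
        precision=(100.0 * cm.tp / (cm.tp + cm.fp)) if cm.tp + cm.fp else float("nan"),
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
    )


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation per metric column.

    A single row yields SD 0 by convention.  Values are full precision;
    round only when reporting.
    """
    if len(rows) == 0:
        raise ValueError("summarize needs at least one row")
    mean = rows[list(METRIC_COLUMNS)].mean()
    sd = rows[list(METRIC_COLUMNS)].std(ddof=1).fillna(0.0)
    return pd.DataFrame({"mean": mean, "sd": sd})


@dataclass
class RunTable:
    """Per-run metrics plus their mean +/- SD summary."""

    rows: pd.DataFrame
    confusions: list[ConfusionMatrix]

    def summary(self) -> pd.DataFrame:
        return summarize(self.rows)

    def formatted_summary(self) -> dict[str, str]:
        s = self.summary()
        return {
            m: f"{round2(s.loc[m, 'mean']):.2f} ± {round2(s.loc[m, 'sd']):.2f}"
            for m in METRIC_COLUMNS
        }


def run_seeds(master_seed: int, n_runs: int) -> list[tuple[int, int, int]]:
    """(split, init, train) seeds per run, derived reproducibly from one master."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for child in ss.spawn(n_runs):
        s = child.generate_state(3, dtype=np.uint32) % (2**31)
        out.append((int(s[0]), int(s[1]), int(s[2])))
    return out


def multirun(dataset: ImageDataset, arch_config: ArchitectureConfig,
             train_config: TrainConfig, n_runs: int = 10,
             holdout: HoldoutSpec | None = None,
             augment_config: AugmentConfig | None = None) -> RunTable:
    """The full repeated-hold-out experiment.

    Each run re-splits the dataset with a fresh derived seed, optionally
    augments the training branch, trains a freshly initialized network and
    evaluates on the held-out test images.  ``augment_config=None`` disables
    augmentation (the ablation arm).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if holdout is None:
        counts = dataset.class_counts()
        holdout = HoldoutSpec(
            train_per_class={c: counts[c] // 2 for c in counts},
            test_per_class={c: counts[c] - counts[c] // 2 for c in counts},
        )
    records = []
    confusions = []
    for split_seed, init_seed, train_seed in run_seeds(train_config.seed, n_runs):
        spec = HoldoutSpec(holdout.train_per_class, holdout.test_per_class, seed=split_seed)
        train_set, test_set = holdout_split(dataset, spec)
        if augment_config is not None:
            aug = AugmentConfig(**{**augment_config.__dict__, "seed": train_seed})
            train_set = augment_training_set(train_set, aug)
        network = build(arch_config, init_seed=init_seed)
        network, _ = train(network, train_set,
                           TrainConfig(**{**train_config.__dict__, "seed": train_seed}))
        cm = evaluate(network, test_set)
        confusions.append(cm)
        records.append(compute_metrics(cm, strict=False).as_tuple())
    rows = pd.DataFrame(records, columns=list(METRIC_COLUMNS))
    rows.index = pd.RangeIndex(1, n_runs + 1, name="run")
    return RunTable(rows=rows, confusions=confusions)
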