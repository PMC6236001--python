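"""Published ten-run benchmark metrics for the MS/HC slice-classification task.

These are the reported per-run hold-out results of the reference 14-layer
network under its three pooling variants — stochastic pooling (the proposed
method), max pooling and average pooling — each over ten repeated random
hold-out runs (326 MS / 331 HC test images per run).  They are the paired
inputs of the pooling comparison: the exact signed-rank test in
:mod:`msnet.stats` operates on matching metric columns of two variants.

Values are percentages as printed (two decimals); summaries recomputed from
these rows use the full rows, not any separately printed averages.
"""

from __future__ import annotations

import pandas as pd

from .train_eval import METRIC_COLUMNS

#: Test-set class sizes of the reference hold-out split.
TEST_MS, TEST_HC = 326, 331
TRAIN_MS, TRAIN_HC = 350, 350

_SP = [
    # sensitivity, specificity, precision, accuracy
    (98.77, 98.19, 98.17, 98.48),
    (98.47, 97.58, 97.57, 98.02),
    (98.47, 98.79, 98.77, 98.63),
    (98.16, 98.79, 98.77, 98.48),
    (99.08, 98.79, 98.78, 98.93),
    (98.77, 98.79, 98.77, 98.78),
    (99.39, 99.40, 99.39, 99.39),
    (99.08, 98.49, 98.48, 98.78),
    (98.77, 99.40, 99.38, 99.09),
    (98.77, 99.40, 99.38, 99.09),
]

_MP = [
    (97.87, 97.87, 97.89, 97.87),
    (98.63, 98.63, 98.66, 98.63),
    (98.18, 98.18, 98.20, 98.17),
    (96.04, 96.04, 96.11, 96.04),
    (96.80, 96.80, 96.86, 96.80),
    (98.78, 98.78, 98.81, 98.78),
    (98.63, 98.63, 98.65, 98.63),
    (97.86, 97.86, 97.88, 97.87),
    (99.24, 99.24, 99.25, 99.24),
    (98.63, 98.63, 98.64, 98.63),
]

_AP = [
    (97.41, 97.41, 97.55, 97.41),
    (96.65, 96.66, 96.67, 96.65),
    (98.33, 98.32, 98.37, 98.33),
    (97.41, 97.41, 97.42, 97.41),
    (96.65, 96.65, 96.65, 96.65),
    (97.87, 97.87, 97.88, 97.87),
    (97.56, 97.57, 97.58, 97.56),
    (97.87, 97.87, 97.92, 97.87),
    (98.48, 98.48, 98.52, 98.48),
    (98.48, 98.47, 98.51, 98.48),
]

_TABLES = {"stochastic": _SP, "max": _MP, "average": _AP}


def pooling_benchmark_runs(pooling: str) -> pd.DataFrame:
    """Per-run benchmark metrics (percent) for one pooling variant.

    ``pooling`` is one of ``stochastic``, ``max``, ``average``.  Rows are in
    the printed run order (1..10), columns are sensitivity, specificity,
    precision, accuracy.
    """
    try:
        rows = _TABLES[pooling]
    except KeyError:
        raise ValueError(f"unknown pooling variant {pooling!r}; "
                         f"expected one of {sorted(_TABLES)}") from None
    df = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    df.index = pd.RangeIndex(1, len(rows) + 1, name="run")
    return df
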