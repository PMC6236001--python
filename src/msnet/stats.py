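"""Exact two-sided Wilcoxon signed-rank test for paired run metrics.

The paired per-run metrics being compared (e.g. accuracies of two pooling
variants over the same ten runs) are few and non-Gaussian, so the
comparison uses the signed-rank test with its *exact* null distribution
rather than the large-sample normal approximation:

1. zero differences are dropped (Wilcoxon's original treatment), leaving
   ``n_effective`` pairs;
2. absolute differences are ranked with average ranks for ties;
3. W = min(W+, W-);
4. the two-sided p-value is 2 * P(W <= observed), computed by exhaustive
   enumeration of all 2^n_effective equally likely sign assignments
   *conditional on the observed (possibly tied) rank vector*, capped at 1.

The enumeration is carried out by an exact generating-function convolution
over the rank vector (ranks doubled so tied half-integer averages become
integers), which tallies the same 2^n sign assignments without looping over
them; a naive 2^n loop is the independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import errors

#: Enumeration bound: 2^n sign assignments must stay exactly countable.
MAX_EXACT_N = 30


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of the exact signed-rank test."""

    w_minus: float
    w_plus: float
    n_effective: int
    p_two_sided: float
    method: str = "exact"

    @property
    def statistic(self) -> float:
        return min(self.w_minus, self.w_plus)


def exact_tail(ranks: Sequence[float], w: float) -> float:
    """P(W- <= w) under independent uniform random signs of the given ranks.

    ``ranks`` may contain tied average ranks (half-integers).  Exact by full
    enumeration of the 2^n sign assignments via convolution of the rank
    generating function.
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    n = ranks.size
    if n == 0:
        return 1.0
    if n > MAX_EXACT_N:
        raise errors.TooLarge(f"exact enumeration limited to n <= {MAX_EXACT_N}, got {n}")
    if (ranks <= 0).any():
        raise ValueError("ranks must be positive")
    doubled = np.rint(2 * ranks).astype(np.int64)
    if not np.allclose(2 * ranks, doubled):
        raise ValueError("ranks must be integers or half-integers")
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()
    threshold = int(np.floor(2 * w + 1e-9))
    return float(counts[: threshold + 1].sum() / 2.0**n)


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    Differences are x - y; zero differences are dropped; ties in |d| get
    average ranks; p = 2 * P(W <= min(W+, W-)) by exact enumeration,
    capped at 1.  All-zero differences yield p = 1 with n_effective = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise errors.LengthMismatch(f"paired samples must match: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise errors.LengthMismatch("paired samples must be non-empty")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(w_minus=0.0, w_plus=0.0, n_effective=0, p_two_sided=1.0)
    ranks = rankdata(np.abs(d))
    w_minus = float(ranks[d < 0].sum())
    w_plus = float(ranks[d > 0].sum())
    p = min(1.0, 2.0 * exact_tail(ranks, min(w_minus, w_plus)))
    return WilcoxonResult(w_minus=w_minus, w_plus=w_plus, n_effective=n, p_two_sided=p)
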