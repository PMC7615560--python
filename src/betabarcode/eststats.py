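"""Estimation statistics: bootstrap effect sizes and permutation tests.

Group differences are reported as an observed mean (or median) difference
with a bootstrap 95% confidence interval (2.5th/97.5th percentiles of the
resampled difference distribution) and a two-sided label-shuffle permutation
p value.  Defaults: 5,000 bootstrap resamples, 10,000 shuffles.  The
permutation p uses +1 smoothing so it can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# two-sided significance tiers: alpha -> percentile threshold applied to each tail
SIGNIFICANCE_PERCENTILES = {0.05: 2.5, 0.01: 0.05, 0.001: 0.0005}


@dataclass
class EstimationResult:
    difference: float
    bootstrap: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float | None
    n_boot: int
    n_shuffle: int
    paired: bool
    statistic: str = "mean"


def _stat(x: np.ndarray, statistic: str) -> float:
    return float(np.median(x)) if statistic == "median" else float(np.mean(x))


def mean_difference_estimate(
    A,
    B,
    paired: bool = False,
    n_boot: int = 5000,
    seed: int = 0,
    statistic: str = "mean",
) -> EstimationResult:
    """Observed difference A - B with a bootstrap 95% CI.

    Unpaired: resample within each group independently.  Paired: resample
    pairs jointly.  ``statistic`` may be 'mean' or 'median' (for skewed
    distributions; caller decides).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty group")
    if paired and len(A) != len(B):
        raise ValueError("paired groups must have equal length")
    rng = np.random.default_rng(seed)
    delta = _stat(A, statistic) - _stat(B, statistic)
    boot = np.empty(n_boot)
    if paired:
        d = A - B
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        for k in range(n_boot):
            boot[k] = _stat(d[idx[k]], statistic)
    else:
        ia = rng.integers(0, len(A), size=(n_boot, len(A)))
        ib = rng.integers(0, len(B), size=(n_boot, len(B)))
        for k in range(n_boot):
            boot[k] = _stat(A[ia[k]], statistic) - _stat(B[ib[k]], statistic)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EstimationResult(
        difference=delta,
        bootstrap=boot,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=None,
        n_boot=n_boot,
        n_shuffle=0,
        paired=paired,
        statistic=statistic,
    )


def shuffle_permutation_p(
    A,
    B,
    paired: bool = False,
    n_shuffle: int = 10000,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """Two-sided permutation p: fraction of |null difference| >= |observed|.

    Unpaired: group labels are shuffled.  Paired: each pair's labels are
    swapped or preserved with equal chance.  +1 smoothing on both counts.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty group")
    if paired and len(A) != len(B):
        raise ValueError("paired groups must have equal length")
    rng = np.random.default_rng(seed)
    obs = abs(_stat(A, statistic) - _stat(B, statistic))
    count = 0
    if paired:
        d = A - B
        signs = rng.choice([-1.0, 1.0], size=(n_shuffle, len(d)))
        for k in range(n_shuffle):
            if abs(_stat(signs[k] * d, statistic)) >= obs:
                count += 1
    else:
        pool = np.concatenate([A, B])
        na = len(A)
        for _ in range(n_shuffle):
            perm = rng.permutation(pool)
            if abs(_stat(perm[:na], statistic) - _stat(perm[na:], statistic)) >= obs:
                count += 1
    return (count + 1) / (n_shuffle + 1)


def cohens_d(A, B) -> float:
    """(mean A - mean B) / pooled SD; the default zone effect size."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 samples per group")
    na, nb = len(A), len(B)
    pooled = np.sqrt(
        ((na - 1) * A.var(ddof=1) + (nb - 1) * B.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((A.mean() - B.mean()) / pooled)


def bonferroni_family_size(n_groups: int, n_conditions: int) -> int:
    """Comparison count for a full groups x conditions family (e.g. 30 x 4)."""
    if n_groups < 1 or n_conditions < 1:
        raise ValueError("counts must be positive")
    return n_groups * n_conditions


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level alpha / m."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons
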