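"""Nonparametric inference utilities: Monte-Carlo permutation test of mean
differences (Fisher-Pitman) and Spearman rank correlation.

The permutation p-value uses the add-one correction
p = (1 + #{permuted |stat| ≥ |observed|}) / (1 + n_iter), so a Monte-Carlo
p is never exactly zero and the test is slightly conservative at small
n_iter. Identical seed ⇒ identical p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PermutationResult:
    observed_stat: float  # difference of group means, mean(x) - mean(y)
    n_iter: int
    p_value: float
    seed: int


def fisher_pitman(x, y, n_iter: int = 1000, seed: int = 0) -> PermutationResult:
    """Two-sided Monte-Carlo permutation test for a difference of means.

    Group labels are permuted ``n_iter`` times with a seeded generator and
    the absolute mean difference compared against the observed one.
    Degenerate input (all values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return PermutationResult(observed_stat=0.0, n_iter=n_iter, p_value=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pooled, (n_iter, pooled.size)).copy(), axis=1)
    stats = perms[:, : x.size].mean(axis=1) - perms[:, x.size :].mean(axis=1)
    # tolerance absorbs float jitter so permutations tied with the observed
    # statistic count as at least as extreme
    tol = 1e-12 * max(1.0, abs(observed))
    n_extreme = int(np.sum(np.abs(stats) >= abs(observed) - tol))
    p = (1 + n_extreme) / (1 + n_iter)
    return PermutationResult(observed_stat=observed, n_iter=n_iter, p_value=float(p), seed=seed)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Constant input has no defined rank correlation: returns NaN with a
    warning rather than raising, so batch pipelines can proceed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)
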