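"""Bootstrap and permutation tests with Bonferroni correction.

All tests are two-sided on the absolute value of the statistic and return
add-one smoothed Monte-Carlo p-values, p = (k + 1) / (B + 1), so p is never
exactly 0 and the tests are (mildly conservatively) valid at any B. The
two-group permutation test switches to exact enumeration of label
assignments whenever the total number of distinct assignments is small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

__all__ = ["ResampleResult", "bootstrap_diff", "permutation_test", "bonferroni"]

#: Exact enumeration is used when C(n_a + n_b, n_a) does not exceed this.
EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class ResampleResult:
    """Outcome of a resampling test.

    ``significant`` is evaluated against ``corrected_alpha`` (alpha / m
    after Bonferroni correction for m comparisons).
    """

    statistic: float
    p_value: float
    n_resamples: int
    method: str
    corrected_alpha: float
    null_quantiles: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "method": self.method,
            "corrected_alpha": self.corrected_alpha,
            "significant": self.significant,
            "null_quantiles": self.null_quantiles,
            "seed": self.seed,
        }


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _null_summary(null: np.ndarray) -> dict[str, float]:
    qs = np.quantile(null, [0.025, 0.5, 0.975])
    return {"q025": float(qs[0]), "q50": float(qs[1]), "q975": float(qs[2])}


def bootstrap_diff(group_a: Sequence[float], group_b: Sequence[float],
                   n_resamples: int = 2000, alpha: float = 0.05,
                   m: int = 1, seed=None) -> ResampleResult:
    """Two-sided bootstrap test for a difference in group means.

    The null distribution is built by resampling trial labels with
    replacement from the pooled data (groups of the original sizes), and
    the p-value is the smoothed fraction of resampled |mean_a - mean_b|
    at least as large as observed.

    Parameters
    ----------
    group_a, group_b
        Per-trial values (spike counts or rates); both non-empty.
    n_resamples
        Number of bootstrap resamples. Fewer than 100 triggers a warning.
    alpha, m
        Nominal level and Bonferroni divisor for the significance flag.
    seed
        Int seed or ``numpy.random.Generator``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_resamples < 100:
        warnings.warn(f"n_resamples={n_resamples} < 100: p-values will be "
                      "coarse", stacklevel=2)
    rng = _as_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    # vectorized resampling: rows are resamples
    idx_a = rng.integers(0, pooled.size, size=(n_resamples, a.size))
    idx_b = rng.integers(0, pooled.size, size=(n_resamples, b.size))
    null = pooled[idx_a].mean(axis=1) - pooled[idx_b].mean(axis=1)
    k = int(np.count_nonzero(np.abs(null) >= abs(observed)))
    p = (k + 1) / (n_resamples + 1)
    return ResampleResult(
        statistic=float(observed), p_value=p, n_resamples=n_resamples,
        method="bootstrap", corrected_alpha=alpha / m,
        null_quantiles=_null_summary(null),
        seed=None if isinstance(seed, np.random.Generator) else seed)


def _mean_diff(groups: Sequence[np.ndarray]) -> float:
    return float(np.mean(groups[0]) - np.mean(groups[1]))


def permutation_test(groups: Sequence[Sequence[float]],
                     statistic: Callable[[Sequence[np.ndarray]], float] | None = None,
                     n_perms: int = 2000, alpha: float = 0.05,
                     m: int = 1, seed=None,
                     method: str = "auto") -> ResampleResult:
    """Label-shuffle permutation test for a statistic over >= 2 groups.

    With ``method="auto"``, two groups are tested by exact enumeration of
    every distinct assignment of observations to group labels whenever
    that is feasible (C(n, n_a) <= 10,000); otherwise, and always for
    > 2 groups, a Monte-Carlo shuffle null with add-one smoothing is
    used. ``method="mc"`` forces the Monte-Carlo path. Two-sided via
    |statistic|.
    """
    if method not in ("auto", "mc"):
        raise ValueError("method must be 'auto' or 'mc'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    stat = statistic if statistic is not None else _mean_diff
    if statistic is None and len(arrays) != 2:
        raise ValueError("default mean-difference statistic requires 2 groups")

    observed = float(stat(arrays))
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]

    def split(perm_pool: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for n in sizes:
            out.append(perm_pool[start:start + n])
            start += n
        return out

    n_total = pooled.size
    exact = (method == "auto" and len(arrays) == 2
             and math.comb(n_total, sizes[0]) <= EXACT_ENUMERATION_LIMIT)
    if exact:
        null = []
        all_idx = frozenset(range(n_total))
        for combo in combinations(range(n_total), sizes[0]):
            ga = pooled[list(combo)]
            gb = pooled[list(sorted(all_idx - set(combo)))]
            null.append(stat([ga, gb]))
        null = np.asarray(null)
        k = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
        p = k / null.size  # exact: observed assignment is in the enumeration
        method = "permutation_exact"
        n_used = null.size
    else:
        rng = _as_rng(seed)
        if statistic is None:
            # vectorized path for the default two-group mean difference
            perms = rng.permuted(
                np.broadcast_to(pooled, (n_perms, n_total)).copy(), axis=1)
            null = (perms[:, :sizes[0]].mean(axis=1)
                    - perms[:, sizes[0]:].mean(axis=1))
        else:
            null = np.empty(n_perms)
            for i in range(n_perms):
                null[i] = stat(split(rng.permutation(pooled)))
        k = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
        p = (k + 1) / (n_perms + 1)
        method = "permutation_mc"
        n_used = n_perms
    return ResampleResult(
        statistic=observed, p_value=float(p), n_resamples=n_used,
        method=method, corrected_alpha=alpha / m,
        null_quantiles=_null_summary(null),
        seed=None if isinstance(seed, np.random.Generator) else seed)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05,
               m: int | None = None) -> np.ndarray:
    """Bonferroni significance flags: p_i < alpha / m.

    ``m`` defaults to the number of tests and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m == 0:
        raise ValueError("m must be positive")
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests ({p.size})")
    return p < alpha / m
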