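"""Permutation tests: paired sign-flip, correlation, and difference in means.

With cohorts of 5-10 animals, exact enumeration of the permutation null is
cheap and reproducible, so each test enumerates exhaustively whenever the
null set is small enough (all 2^n sign patterns, all n! orderings, or all
C(n, n_a) label assignments) and falls back to seeded Monte Carlo otherwise.
Exhaustive p-values are exact rational multiples of the pattern count and
include the identity arrangement; Monte-Carlo p-values use the add-one
correction p = (k + 1) / (B + 1), which cannot return zero. Ties in
|statistic| between a permuted arrangement and the observed one count toward
the numerator (>=, the conservative convention), with a tiny relative
tolerance so exact ties survive floating-point evaluation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError

__all__ = [
    "PermutationResult",
    "paired_signflip_test",
    "perm_corr_test",
    "perm_meandiff_test",
]

#: Largest exhaustive null set for sign flips (2^20 patterns).
MAX_EXHAUSTIVE_SIGNFLIP = 2**20
#: Largest exhaustive null set for orderings / label assignments.
MAX_EXHAUSTIVE_PERMS = 10**6

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    p_value: float
    n_permutations_used: int
    method: str  # "exhaustive" | "monte_carlo"
    seed: int | None = None


def _two_sided_count(perm_stats: np.ndarray, observed: float) -> int:
    """Count permuted |stat| >= |observed| with a relative tie tolerance."""
    thr = abs(observed) * (1.0 - _TIE_RTOL) - 1e-300
    return int(np.count_nonzero(np.abs(perm_stats) >= thr))


def _resolve_method(method: str, feasible: bool) -> bool:
    """True -> exhaustive. ``method`` is auto|exhaustive|monte_carlo."""
    if method == "auto":
        return feasible
    if method == "exhaustive":
        if not feasible:
            raise ValidationError("exhaustive enumeration infeasible for this input size")
        return True
    if method == "monte_carlo":
        return False
    raise ValidationError(f"unknown method {method!r}")


def paired_signflip_test(
    differences,
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided paired sign-flip test on the mean of within-pair differences.

    The null hypothesis of a symmetric-about-zero difference distribution is
    simulated by independently negating each difference; the statistic is the
    mean difference (the Delta-mean reported alongside the p-value).
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValidationError("differences must be non-empty")
    n = d.size
    observed = float(np.mean(d))
    if _resolve_method(method, 2**n <= MAX_EXHAUSTIVE_SIGNFLIP):
        total = 2**n
        count = 0
        chunk = 1 << 16
        codes = np.arange(total, dtype=np.int64)
        bits = np.arange(n, dtype=np.int64)
        for start in range(0, total, chunk):
            block = codes[start : start + chunk]
            signs = 1.0 - 2.0 * ((block[:, None] >> bits) & 1)
            count += _two_sided_count(signs @ d / n, observed)
        return PermutationResult(observed, count / total, total, "exhaustive")
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, n))
    k = _two_sided_count(signs @ d / n, observed)
    p = (k + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, "monte_carlo", seed)


def _pearson_against_perms(x: np.ndarray, y_perms: np.ndarray) -> np.ndarray:
    n = x.size
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y_perms - y_perms.mean(axis=1, keepdims=True)) / y_perms.std(
        axis=1, ddof=1, keepdims=True
    )
    return zy @ zx / (n - 1)


def perm_corr_test(
    x, y, n_permutations: int = 10_000, seed: int | None = None, method: str = "auto"
) -> PermutationResult:
    """Two-sided permutation test on the Pearson correlation coefficient.

    The null of no association is simulated by permuting y against fixed x.
    Exhaustive over all n! orderings when n! <= 10^6 (n <= 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("x and y must be equal-length with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in x or y; correlation is degenerate")
    n = x.size
    observed = float(np.corrcoef(x, y)[0, 1])
    if _resolve_method(method, math.factorial(n) <= MAX_EXHAUSTIVE_PERMS):
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        stats = _pearson_against_perms(x, y[perms])
        k = _two_sided_count(stats, observed)
        return PermutationResult(observed, k / len(perms), len(perms), "exhaustive")
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    k = _two_sided_count(_pearson_against_perms(x, y[idx]), observed)
    p = (k + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, "monte_carlo", seed)


def perm_meandiff_test(
    group_a, group_b, n_permutations: int = 10_000, seed: int | None = None, method: str = "auto"
) -> PermutationResult:
    """Two-sided permutation test on mean(a) - mean(b).

    Group labels are reshuffled preserving group sizes; exhaustive over all
    C(n, n_a) assignments when that count is <= 10^6.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(a.mean() - b.mean())
    total_sum = pooled.sum()
    n_b = n - na

    def stat_from_a_sums(a_sums: np.ndarray) -> np.ndarray:
        return a_sums / na - (total_sum - a_sums) / n_b

    if _resolve_method(method, math.comb(n, na) <= MAX_EXHAUSTIVE_PERMS):
        combos = itertools.combinations(range(n), na)
        a_sums = np.fromiter(
            (pooled[list(c)].sum() for c in combos), dtype=float, count=math.comb(n, na)
        )
        k = _two_sided_count(stat_from_a_sums(a_sums), observed)
        return PermutationResult(observed, k / a_sums.size, a_sums.size, "exhaustive")
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :na]
    a_sums = pooled[idx].sum(axis=1)
    k = _two_sided_count(stat_from_a_sums(a_sums), observed)
    p = (k + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, "monte_carlo", seed)
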