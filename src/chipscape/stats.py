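"""Shared statistical primitives.

Three tests recur across the pipeline and are centralized here so their
conventions are stated once:

* an upper-tail Poisson probability for peak scoring,
* an exact two-sided binomial test against 0.5 for allelic skew, using the
  minimum-likelihood convention (sum the probabilities of all outcomes no
  more likely than the observed one),
* a two-sided Wilcoxon rank-sum test that is exact by enumeration for small
  samples and normal-approximated (tie- and continuity-corrected) otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as _st

EXACT_RANKSUM_MAX_N = 12  # pooled size at or below which the null is enumerated


def poisson_upper_tail(count: int, lam: float) -> float:
    """P(X >= count) for X ~ Poisson(lam).

    Computed via the regularized upper incomplete gamma function (survival
    function), which is stable in log space for large counts.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if count == 0:
        return 1.0
    return float(_st.poisson.sf(count - 1, lam))


def poisson_upper_tail_vec(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Vectorized P(X >= count); counts of 0 map to 1."""
    counts = np.asarray(counts)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive everywhere")
    return _st.poisson.sf(counts - 1, lam)


def binom_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood convention."""
    if n == 0:
        raise ValueError("binomial test undefined for n = 0")
    return float(_st.binomtest(k, n, p, alternative="two-sided").pvalue)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    All C(n_a+n_b, n_a) ways of assigning the pooled observations to group a
    are enumerated; p = 2 * min(P(W <= w_obs), P(W >= w_obs)) capped at 1,
    where W is group a's rank sum. Ties are handled naturally because the
    observed pooled multiset (midranked) is what gets permuted.
    """
    pooled = np.concatenate([a, b])
    ranks = _st.rankdata(pooled)  # midranks under ties
    n_a = len(a)
    w_obs = float(ranks[:n_a].sum())
    n = len(pooled)
    total = comb(n, n_a)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        w = float(ranks[list(idx)].sum())
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration when the pooled sample size is at most
    EXACT_RANKSUM_MAX_N, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test undefined for an empty group")
    if len(a) + len(b) <= EXACT_RANKSUM_MAX_N:
        return _exact_ranksum_p(a, b)
    res = _st.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)
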