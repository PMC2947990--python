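"""Shared statistical primitives.

The detection call, the enrichment tests and the profile shift test all
reduce to a handful of classical exact tests.  They are implemented here
once, with vectorised fast paths where the pipeline calls them tens of
thousands of times (one Wilcoxon signed-rank test per gene per array),
and are cross-checked in the test-suite against brute-force enumeration
and against scipy's scalar implementations.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "signed_rank_statistic",
    "signed_rank_p_greater",
    "signed_rank_exact_sf",
    "binom_minlike_p",
    "binom_tail_p",
    "hypergeom_two_sided_p",
]

# Exact enumeration of the signed-rank null is cheap below this many
# nonzero differences; above it a tie-corrected normal approximation
# with continuity correction takes over.
EXACT_LIMIT = 20


@functools.lru_cache(maxsize=64)
def _signed_rank_tail_table(n: int) -> np.ndarray:
    """Upper-tail counts of the exact W+ null distribution for ``n`` pairs.

    Entry ``t[w]`` is the number of the 2**n sign assignments whose
    positive-rank sum is >= w, for w in 0..n(n+1)/2.  Built by the usual
    subset-sum dynamic programme over ranks 1..n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=np.float64)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    # cumulative from the top: number of assignments with W+ >= w
    return np.cumsum(counts[::-1])[::-1]


def signed_rank_exact_sf(w: float, n: int) -> float:
    """Exact one-sided P(W+ >= w) for n untied, nonzero paired differences."""
    table = _signed_rank_tail_table(n)
    wc = int(math.ceil(w - 1e-9))
    if wc <= 0:
        return 1.0
    if wc > n * (n + 1) // 2:
        return 0.0
    return float(table[wc] / 2.0**n)


def signed_rank_statistic(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive-rank sums for a matrix of paired differences.

    Parameters
    ----------
    diff : (n_pairs, n_units) array
        One column per test unit; zeros are dropped per column
        (Wilcoxon's original zero handling).

    Returns
    -------
    w_plus, n_nonzero, tie_term : arrays of shape (n_units,)
        ``tie_term`` is sum(t^3 - t) over tie groups of |diff|,
        needed for the variance correction of the normal approximation.
    """
    diff = np.asarray(diff, dtype=float)
    n_pairs, n_units = diff.shape
    w_plus = np.empty(n_units)
    n_nonzero = np.empty(n_units, dtype=int)
    tie_term = np.empty(n_units)
    for j in range(n_units):
        d = diff[:, j]
        d = d[d != 0.0]
        n_nonzero[j] = d.size
        if d.size == 0:
            w_plus[j] = 0.0
            tie_term[j] = 0.0
            continue
        ranks = sps.rankdata(np.abs(d))
        w_plus[j] = ranks[d > 0].sum()
        _, t = np.unique(np.abs(d), return_counts=True)
        tie_term[j] = float((t**3 - t).sum())
    return w_plus, n_nonzero, tie_term


def signed_rank_p_greater(pm: np.ndarray, mm: np.ndarray) -> np.ndarray:
    """One-sided Wilcoxon signed-rank p-values, columns are test units.

    Tests whether the paired differences ``pm - mm`` are shifted above
    zero.  Exact when a column has fewer than ``EXACT_LIMIT`` nonzero,
    untied differences; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    w_plus, n_nz, tie_term = signed_rank_statistic(pm - mm)
    p = np.ones(w_plus.shape)
    for j in range(p.size):
        n = int(n_nz[j])
        if n == 0:
            continue
        if n < EXACT_LIMIT and tie_term[j] == 0.0:
            p[j] = signed_rank_exact_sf(w_plus[j], n)
        else:
            mean = n * (n + 1) / 4.0
            var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term[j] / 48.0
            if var <= 0.0:
                p[j] = 1.0
                continue
            z = (w_plus[j] - mean - 0.5) / math.sqrt(var)
            p[j] = float(sps.norm.sf(z))
    return p


def binom_minlike_p(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by the minimum-likelihood rule.

    Sums P(X = i) over all outcomes i whose point probability does not
    exceed that of the observed count (R's ``binom.test`` convention).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"expected proportion must lie in [0, 1], got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"observed count {k} outside [0, {n}]")
    if n == 0:
        return 1.0
    i = np.arange(n + 1)
    pmf = sps.binom.pmf(i, n, p)
    # relative tolerance mirrors R's binom.test
    return float(min(1.0, pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum()))


def binom_tail_p(k: int, n: int, p: float) -> float:
    """One-sided exact binomial tail in the direction of the deviation."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"expected proportion must lie in [0, 1], got {p}")
    if n == 0:
        return 1.0
    if k >= n * p:
        return float(sps.binom.sf(k - 1, n, p))
    return float(sps.binom.cdf(k, n, p))


def hypergeom_two_sided_p(k: int, N: int, K: int, n: int) -> float:
    """Two-sided hypergeometric p as the doubled smaller tail, capped at 1.

    ``k`` marked genes drawn in a sample of ``n`` from a universe of
    ``N`` genes of which ``K`` are marked.
    """
    lower = float(sps.hypergeom.cdf(k, N, K, n))
    upper = float(sps.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, 2.0 * min(lower, upper))
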