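"""Gene-by-gene two-group contrasts with exhaustive permutation FDR.

The study design has three replicates per genotype, so every pairwise
contrast admits only ten distinct relabelings of its six samples.  The
false-discovery rate of a contrast is estimated non-parametrically as

    FDR = median over relabelings of (#significant genes) / #observed

with the observed labeling included among the relabelings.  A
Benjamini-Hochberg step-up cutoff is also provided for translating a
target FDR into a per-gene p-value threshold (a pragmatic substitute
for density-based local-fdr estimators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix

__all__ = [
    "ContrastResult",
    "FdrEstimate",
    "ttest_contrast",
    "enumerate_relabelings",
    "permutation_fdr",
    "fdr_threshold",
]


@dataclass
class ContrastResult:
    """Per-gene equal-variance t-test results for one genotype contrast.

    ``table`` is indexed by gene_id with columns t_statistic, p_value,
    mean_diff_log2 (group A minus group B) and direction; genes with no
    variation in either group are excluded and listed separately.
    """

    contrast_name: str
    group_a: str
    group_b: str
    table: pd.DataFrame
    excluded_genes: set[str] = field(default_factory=set)

    def significant(self, alpha: float) -> set[str]:
        return set(self.table.index[self.table["p_value"] < alpha])

    def n_significant(self, alpha: float) -> int:
        return int((self.table["p_value"] < alpha).sum())


@dataclass
class FdrEstimate:
    contrast_name: str
    alpha: float
    n_observed_significant: int
    permutation_counts: list[int]
    fdr: float | None  # None when no observed significant genes

    @property
    def defined(self) -> bool:
        return self.fdr is not None


def _ttest_arrays(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Row-wise two-sample t on (genes x replicates) arrays.

    Returns (t, p, mean_diff, zero_variance_mask); two-sided p with
    n_a + n_b - 2 degrees of freedom for the pooled test.
    """
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    zero_var = (va == 0.0) & (vb == 0.0)
    with warnings.catch_warnings():
        # near-constant genes are excluded via zero_var; silence scipy's
        # precision-loss warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    return t, p, mean_diff, zero_var


def ttest_contrast(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> ContrastResult:
    """Equal-variance Student t-test per gene between two genotypes."""
    cols_a = matrix.samples_of(group_a)
    cols_b = matrix.samples_of(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both genotypes need at least two replicates")
    a = matrix.values[cols_a].to_numpy(float)
    b = matrix.values[cols_b].to_numpy(float)
    t, p, mean_diff, zero_var = _ttest_arrays(a, b, equal_var=equal_var)
    genes = matrix.values.index
    keep = ~zero_var
    table = pd.DataFrame(
        {
            "t_statistic": t[keep],
            "p_value": p[keep],
            "mean_diff_log2": mean_diff[keep],
            "direction": np.where(mean_diff[keep] >= 0, "up_in_A", "down_in_A"),
        },
        index=genes[keep],
    )
    return ContrastResult(
        contrast_name=f"{group_a}_vs_{group_b}",
        group_a=group_a,
        group_b=group_b,
        table=table,
        excluded_genes=set(genes[zero_var]),
    )


def enumerate_relabelings(n_a: int, n_b: int) -> list[tuple[int, ...]]:
    """All distinct splits of n_a + n_b pooled samples into the two groups.

    Each relabeling is the tuple of pooled indices assigned to group A.
    For equal group sizes a split and its complement define the same
    two-sample test, so only one of each pair is kept — 10 relabelings
    for the study's 3 vs 3 design.  The observed labeling (first n_a
    indices) is always first.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two samples per group")
    n = n_a + n_b
    pool = range(n)
    labelings: list[tuple[int, ...]] = []
    seen: set[frozenset[int]] = set()
    for c in combinations(pool, n_a):
        if n_a == n_b:
            comp = frozenset(set(pool) - set(c))
            if frozenset(c) in seen or comp in seen:
                continue
            seen.add(frozenset(c))
        labelings.append(c)
    observed = tuple(range(n_a))
    labelings.sort(key=lambda c: c != observed)  # observed first
    expected = comb(n, n_a) // 2 if n_a == n_b else comb(n, n_a)
    assert len(labelings) == expected
    return labelings


def permutation_fdr(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> FdrEstimate:
    """Exhaustive-relabeling FDR estimate for one contrast.

    Runs the gene-by-gene t-test under every distinct relabeling of the
    pooled samples (full enumeration, no sampling, hence deterministic)
    and reports median(#significant under relabeling) / #observed.
    Zero-variance genes are re-excluded under each relabeling.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    cols = matrix.samples_of(group_a) + matrix.samples_of(group_b)
    n_a = len(matrix.samples_of(group_a))
    n_b = len(cols) - n_a
    pooled = matrix.values[cols].to_numpy(float)
    counts = []
    for labeling in enumerate_relabelings(n_a, n_b):
        in_a = np.zeros(n_a + n_b, dtype=bool)
        in_a[list(labeling)] = True
        _, p, _, zero_var = _ttest_arrays(
            pooled[:, in_a], pooled[:, ~in_a], equal_var=equal_var
        )
        counts.append(int((p[~zero_var] < alpha).sum()))
    n_observed = counts[0]
    fdr = None if n_observed == 0 else float(np.median(counts)) / n_observed
    return FdrEstimate(
        contrast_name=f"{group_a}_vs_{group_b}",
        alpha=alpha,
        n_observed_significant=n_observed,
        permutation_counts=counts,
        fdr=fdr,
    )


def fdr_threshold(p_values, q: float = 0.05) -> float:
    """Benjamini-Hochberg step-up p-value cutoff for target FDR ``q``.

    Returns the largest p(i) with p(i) <= q * i / m, or 0.0 when no
    p-value qualifies (the no-discovery sentinel).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    p_sorted = np.sort(p)
    m = p.size
    crit = q * np.arange(1, m + 1) / m
    passing = p_sorted[p_sorted <= crit]
    return float(passing[-1]) if passing.size else 0.0
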