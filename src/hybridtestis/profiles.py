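"""Chromosome-wide expression deviation profiles and X-vs-autosome shifts.

The deviation profile asks, for each genotype and chromosome, how far
genes sit from their own typical level: every gene is anchored at its
median log2 expression across all twelve males, each genotype's mean is
expressed as a deviation from that shared anchor, and deviations are
averaged per chromosome (reported both on the log2 scale and as the
back-transformed percent change 100*(2^d - 1)).

The shift test compares, for one pairwise genotype contrast, the
distribution of per-gene mean log2 differences on the X chromosome
against the pooled autosomes with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix, annotation_index, is_autosomal

logger = logging.getLogger(__name__)

MIN_X_GENES = 5


@dataclass
class DeviationProfile:
    """Per-gene and per-chromosome deviations from the shared gene anchor."""

    per_gene: pd.DataFrame          # genes x genotypes, log2 deviations
    chromosome_table: pd.DataFrame  # genotype, chromosome, n_genes, mean_dev_log2, percent
    gene_median: pd.Series          # the per-gene anchor

    def percent(self, genotype: str, chromosome: str) -> float:
        t = self.chromosome_table
        row = t[(t["genotype"] == genotype) & (t["chromosome"] == str(chromosome))]
        if row.empty:
            raise KeyError(f"no profile entry for {genotype} / {chromosome}")
        return float(row["percent"].iloc[0])


@dataclass
class ShiftTest:
    genotype_a: str
    genotype_b: str
    statistic: float
    p_value: float
    n_x: int
    n_autosome: int
    unreliable: bool = False


def chromosome_deviation_profile(
    matrix: ExpressionMatrix, annotations: pd.DataFrame
) -> DeviationProfile:
    """Average per-chromosome deviation of each genotype from gene anchors."""
    median = matrix.values.median(axis=1)
    means = matrix.genotype_means()
    per_gene = means.sub(median, axis=0)

    ann = annotation_index(annotations)
    chrom = ann.loc[per_gene.index, "chromosome"].astype(str)
    rows = []
    for genotype in per_gene.columns:
        dev = per_gene[genotype]
        for c, grp in dev.groupby(chrom):
            if len(grp) == 0:
                continue
            d = float(grp.mean())
            rows.append((genotype, c, len(grp), d, 100.0 * (2.0**d - 1.0)))
    table = pd.DataFrame(
        rows, columns=["genotype", "chromosome", "n_genes", "mean_dev_log2", "percent"]
    )
    return DeviationProfile(per_gene=per_gene, chromosome_table=table, gene_median=median)


def pairwise_shift_ks(
    matrix: ExpressionMatrix,
    genotype_a: str,
    genotype_b: str,
    annotations: pd.DataFrame,
) -> ShiftTest:
    """KS test of X-linked vs autosomal per-gene mean log2 differences."""
    means = matrix.genotype_means()
    for g in (genotype_a, genotype_b):
        if g not in means.columns:
            raise ValueError(f"genotype {g} missing from matrix")
    diff = means[genotype_a] - means[genotype_b]
    ann = annotation_index(annotations)
    chrom = ann.loc[diff.index, "chromosome"].astype(str)
    x_diff = diff[(chrom == "X").to_numpy()]
    auto_diff = diff[is_autosomal(chrom)]
    unreliable = len(x_diff) < MIN_X_GENES
    if unreliable:
        logger.warning(
            "only %d X-linked genes; KS p-value unreliable", len(x_diff)
        )
    stat, p = sps.ks_2samp(x_diff.to_numpy(), auto_diff.to_numpy(), method="auto")
    return ShiftTest(
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        statistic=float(stat),
        p_value=float(p),
        n_x=len(x_diff),
        n_autosome=len(auto_diff),
        unreliable=unreliable,
    )


def all_pairwise_shifts(matrix: ExpressionMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """The six pairwise genotype KS shift tests as one table."""
    present = list(dict.fromkeys(matrix.sample_meta["genotype"]))
    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            r = pairwise_shift_ks(matrix, a, b, annotations)
            rows.append((f"{a}_vs_{b}", r.statistic, r.p_value, r.n_x, r.n_autosome,
                         r.unreliable))
    return pd.DataFrame(
        rows, columns=["contrast", "ks_statistic", "p_value", "n_x", "n_autosome",
                       "unreliable"]
    )


def plot_deviation_profile(profile: DeviationProfile, genotype: str, ax=None):
    """Bar chart of per-chromosome percent deviations, X highlighted."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(8, 3))
    t = profile.chromosome_table
    sub = t[t["genotype"] == genotype].copy()
    order = sorted(
        sub["chromosome"], key=lambda c: (not c.isdigit(), int(c) if c.isdigit() else 99)
    )
    sub = sub.set_index("chromosome").loc[order]
    colors = ["crimson" if c == "X" else "steelblue" for c in sub.index]
    ax.bar(range(len(sub)), sub["percent"], color=colors)
    ax.set_xticks(range(len(sub)), sub.index)
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_ylabel("% deviation from gene median")
    ax.set_title(f"Per-chromosome deviation, {genotype}")
    return ax


def plot_shift_distributions(matrix: ExpressionMatrix, annotations: pd.DataFrame,
                             genotype_a: str, genotype_b: str, ax=None):
    """Empirical distributions of per-gene differences, X vs autosomes."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 3))
    means = matrix.genotype_means()
    diff = means[genotype_a] - means[genotype_b]
    ann = annotation_index(annotations)
    chrom = ann.loc[diff.index, "chromosome"].astype(str)
    ax.hist(diff[is_autosomal(chrom)], bins=40, density=True, alpha=0.6,
            color="steelblue", label="autosomes")
    ax.hist(diff[(chrom == "X").to_numpy()], bins=20, density=True, alpha=0.6,
            color="crimson", label="X")
    ax.set_xlabel(f"mean log2 difference ({genotype_a} - {genotype_b})")
    ax.legend()
    return ax
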