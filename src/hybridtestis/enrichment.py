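"""Chromosome-wise and cell-type enrichment tests.

Two families of tests:

* chromosome-wise hypergeometric tests of a gene set against the
  expressed-gene universe, Bonferroni-corrected across chromosomes;
* exact binomial tests of the cell-class composition of a gene panel
  against the class mix of the expressed universe, computed separately
  for the X chromosome and the autosomes (X-linked spermatogenic
  expression is strongly non-random across cell types, so a pooled
  expectation would be confounded).

The binomial convention — a two-sided minimum-likelihood exact p
(R ``binom.test``) multiplied by the number of cell classes tested
within the stratum (4 autosomal, 3 X-linked; the X has no meiotic
genes) — was fixed by calibration against the study's published tables
and is documented as inferred rather than stated.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import CELL_CLASSES, ExpressionMatrix, annotation_index, is_autosomal
from .stats import binom_minlike_p, binom_tail_p, hypergeom_two_sided_p

logger = logging.getLogger(__name__)

STRATA = ("autosomes", "X")
BINOMIAL_TAILS = ("minlike", "one_sided")


def chromosome_enrichment(
    gene_set, universe, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome over/under-representation of ``gene_set``.

    Expected counts are n*K/N for a set of size n drawn from a universe
    of N genes with K on the chromosome; p-values are two-sided
    hypergeometric (doubled smaller tail) with Bonferroni correction
    across the chromosomes tested.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    ann = annotation_index(annotations)
    missing = universe - set(ann.index)
    if missing:
        raise ValueError(f"universe genes lack annotation: {sorted(missing)[:5]}")
    chrom = ann.loc[list(universe), "chromosome"].astype(str)
    in_set = chrom.index.isin(gene_set)
    N, n = len(universe), len(gene_set)

    rows = []
    testable = [c for c in chrom.unique() if (chrom == c).sum() > 0]
    family = len(testable)
    for c in sorted(testable, key=lambda x: (x not in map(str, range(1, 20)), x.zfill(2))):
        K = int((chrom == c).sum())
        if K == 0:
            logger.warning("chromosome %s has no universe genes; skipped", c)
            continue
        k = int((in_set & (chrom == c)).sum())
        expected = n * K / N
        p = min(1.0, hypergeom_two_sided_p(k, N, K, n) * family)
        rows.append((c, K, k, expected, p))
    table = pd.DataFrame(
        rows, columns=["chromosome", "universe_genes", "observed", "expected", "p_corrected"]
    )
    table.attrs["family_size"] = family
    return table


def celltype_expected(
    universe_counts_by_class, panel_total: int, stratum: str = "autosomes"
) -> pd.Series:
    """Expected class counts for a panel, from the stratum's universe mix."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    u = pd.Series(universe_counts_by_class, dtype=float)
    if (u < 0).any():
        raise ValueError("universe counts must be nonnegative")
    total = u.sum()
    if total == 0:
        raise ValueError(f"no universe genes in stratum {stratum}")
    return panel_total * u / total


def celltype_binomial(
    observed: int,
    panel_total: int,
    expected_proportion: float,
    family_size: int,
    tail: str = "minlike",
) -> float:
    """Bonferroni-corrected exact binomial p for one panel cell.

    ``tail='minlike'`` is the calibrated default (two-sided
    minimum-likelihood); ``'one_sided'`` is the exact tail toward the
    observed deviation.
    """
    if observed > panel_total:
        raise ValueError("observed exceeds panel total")
    if tail not in BINOMIAL_TAILS:
        raise ValueError(f"unknown tail {tail!r}")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if tail == "minlike":
        p = binom_minlike_p(observed, panel_total, expected_proportion)
    else:
        p = binom_tail_p(observed, panel_total, expected_proportion)
    return min(1.0, family_size * p)


def _stratum_mask(ann: pd.DataFrame, stratum: str) -> np.ndarray:
    chrom = ann["chromosome"].astype(str).to_numpy()
    return is_autosomal(chrom) if stratum == "autosomes" else chrom == "X"


def celltype_enrichment_table(
    panels: dict[str, set[str]],
    universe,
    annotations: pd.DataFrame,
    tail: str = "minlike",
) -> pd.DataFrame:
    """Cell-class composition tests for a family of gene panels.

    ``panels`` maps a panel name (e.g. ``all``, ``higher``, ``lower``,
    ``intermediate``) to its gene set.  For each panel and stratum
    (autosomes, X) every cell class with expressed-universe members is
    tested against the stratum's universe class mix; the Bonferroni
    family is the number of classes tested within the stratum.  Genes
    without a cell-class label (and Y-linked genes) are outside the
    panel universe.
    """
    ann = annotation_index(annotations)
    universe = set(universe)
    u_ann = ann.loc[ann.index.isin(universe)]
    u_ann = u_ann[u_ann["cell_class"].isin(CELL_CLASSES)]

    rows = []
    for stratum in STRATA:
        in_stratum = u_ann[_stratum_mask(u_ann, stratum)]
        u_counts = in_stratum["cell_class"].value_counts().reindex(
            CELL_CLASSES, fill_value=0
        )
        tested = [c for c in CELL_CLASSES if u_counts[c] > 0]
        family = len(tested)
        if family == 0:
            logger.warning("no assignable universe genes in stratum %s", stratum)
            continue
        for panel_name, genes in panels.items():
            members = in_stratum.loc[in_stratum.index.isin(set(genes))]
            panel_total = len(members)
            expected = celltype_expected(u_counts[tested], panel_total, stratum)
            obs_counts = members["cell_class"].value_counts().reindex(
                tested, fill_value=0
            )
            for cls in tested:
                prop = u_counts[cls] / u_counts[tested].sum()
                p = celltype_binomial(
                    int(obs_counts[cls]), panel_total, prop, family, tail=tail
                )
                rows.append(
                    (panel_name, stratum, cls, panel_total,
                     int(obs_counts[cls]), float(expected[cls]), p, family)
                )
    return pd.DataFrame(
        rows,
        columns=["panel", "stratum", "cell_class", "panel_total",
                 "observed", "expected", "p_corrected", "family_size"],
    )


@dataclass
class XClassBias:
    """Per X-expression-class counts of genes higher in one genotype."""

    table: pd.DataFrame
    genotype_a: str
    genotype_b: str


def xclass_bias(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    genotype_a: str = "MxD",
    genotype_b: str = "MxM",
) -> XClassBias:
    """Direction bias of X-linked expression between two genotypes.

    For each X-expression class (A, B, C, E — the small 'variable'
    class D is excluded) and pooled across them, counts how many genes
    have higher mean expression in ``genotype_a`` and tests the
    proportion against 1/2 with a two-sided exact binomial.  An
    autosomal row is reported alongside as the no-X-effect reference.
    """
    ann = annotation_index(annotations)
    common = ann.loc[ann.index.isin(set(matrix.gene_ids))]
    means = matrix.genotype_means()
    diff = means[genotype_a] - means[genotype_b]

    def _row(label: str, genes: pd.Index):
        n = len(genes)
        if n == 0:
            logger.warning("x-class %s empty; skipped", label)
            return None
        n_higher = int((diff.loc[genes] > 0).sum())
        p = float(sps.binomtest(n_higher, n, 0.5).pvalue)
        return (label, n, n_higher, n_higher / n, p)

    rows = []
    on_x = common["chromosome"].astype(str) == "X"
    pooled_idx = []
    for cls in ("A", "B", "C", "E"):
        genes = common.index[on_x & (common["x_class"] == cls)]
        pooled_idx.extend(genes)
        r = _row(cls, genes)
        if r:
            rows.append(r)
    r = _row("pooled_X", pd.Index(pooled_idx))
    if r:
        rows.append(r)
    autosomal = common.index[is_autosomal(common["chromosome"])]
    r = _row("autosomes", autosomal)
    if r:
        rows.append(r)
    table = pd.DataFrame(
        rows, columns=["category", "n", "n_higher", "prop_higher", "p_value"]
    )
    return XClassBias(table=table, genotype_a=genotype_a, genotype_b=genotype_b)
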