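"""Protein-evolution rates of X-linked versus autosomal testis genes.

Consumes a precomputed per-gene dN/dS table (estimating rates from
alignments is out of scope) and compares the X-linked and autosomal
strata with a Mann-Whitney rank-sum test.  The comparison is between
two disjoint gene sets, so the unpaired rank-sum test is the coherent
choice even though per-gene rates are themselves derived from pairwise
species alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import annotation_index, is_autosomal

DNDS_COLUMNS = ("gene_id", "dn", "ds", "dnds")


@dataclass
class DndsComparison:
    p_value: float
    statistic: float
    summary: pd.DataFrame  # per stratum: n, mean, median


def validate_dnds(records: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    missing = set(DNDS_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"dN/dS table lacks columns: {sorted(missing)}")
    if (records["ds"] <= 0).any():
        raise ValueError("dS must be positive")
    if (records["dn"] < 0).any():
        raise ValueError("dN must be nonnegative")
    ratio = records["dn"] / records["ds"]
    if (np.abs(ratio - records["dnds"]) > tol * np.maximum(1.0, ratio)).any():
        raise ValueError("dnds column inconsistent with dn/ds")
    return records


def dnds_rank_compare(
    records: pd.DataFrame, annotations: pd.DataFrame
) -> DndsComparison:
    """Rank-sum comparison of dN/dS between X-linked and autosomal genes."""
    records = validate_dnds(records)
    ann = annotation_index(annotations)
    missing = set(records["gene_id"]) - set(ann.index)
    if missing:
        raise ValueError(f"records lack annotation: {sorted(missing)[:5]}")
    chrom = ann.loc[records["gene_id"], "chromosome"].astype(str).to_numpy()
    x_vals = records.loc[chrom == "X", "dnds"].to_numpy(float)
    a_vals = records.loc[is_autosomal(chrom), "dnds"].to_numpy(float)
    if x_vals.size == 0 or a_vals.size == 0:
        raise ValueError("both strata must be non-empty")
    stat, p = sps.mannwhitneyu(x_vals, a_vals, alternative="two-sided")
    summary = pd.DataFrame(
        {
            "n": [x_vals.size, a_vals.size],
            "mean": [x_vals.mean(), a_vals.mean()],
            "median": [np.median(x_vals), np.median(a_vals)],
        },
        index=["X", "autosomes"],
    )
    return DndsComparison(p_value=float(p), statistic=float(stat), summary=summary)
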