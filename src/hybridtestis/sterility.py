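"""Hierarchical definition of sterility-correlated genes.

Rather than adjusting per-gene p-values, the study controls false
discovery hierarchically: a gene counts as sterility-correlated when it
differs between the reciprocal F1 hybrids (sterile MxD vs fertile DxM)
*and* between the sterile hybrid and at least one parental genotype.
Stricter variants require all three sterile-vs-fertile contrasts, or
additionally no difference among the fertile genotypes themselves.
Members are then binned by where the sterile genotype's mean expression
sits relative to the three fertile genotype means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import ContrastResult
from .matrix import ExpressionMatrix, FERTILE_GENOTYPES, STERILE_GENOTYPE

MODES = ("hybrid_and_one_parent", "all_three", "all_three_clean")

STERILE_CONTRASTS = tuple(f"{STERILE_GENOTYPE}_vs_{g}" for g in ("DxM", "MxM", "DxD"))
FERTILE_CONTRASTS = ("MxM_vs_DxD", "DxM_vs_DxD", "DxM_vs_MxM")

DIRECTIONS = ("higher", "lower", "intermediate")


@dataclass
class SterilitySet:
    mode: str
    gene_ids: set[str]
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction:
            missing = self.gene_ids - set(self.direction)
            if missing:
                raise ValueError(f"{len(missing)} members lack a direction bin")

    def members(self, direction: str) -> set[str]:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        return {g for g in self.gene_ids if self.direction.get(g) == direction}


def _normalize_key(name: str) -> frozenset[str]:
    a, _, b = name.partition("_vs_")
    return frozenset((a, b))


def _lookup(contrasts: dict[str, ContrastResult], name: str) -> ContrastResult:
    """Find a contrast by genotype pair, tolerant of A-vs-B orientation."""
    want = _normalize_key(name)
    for c in contrasts.values():
        if _normalize_key(c.contrast_name) == want:
            return c
    raise KeyError(f"contrast {name} missing (have: {sorted(contrasts)})")


def select_sterility_correlated(
    contrasts: dict[str, ContrastResult],
    mode: str = "hybrid_and_one_parent",
    alpha: float = 0.05,
) -> SterilitySet:
    """Apply the hierarchical selection scheme at per-contrast level alpha.

    Significance is the unadjusted per-contrast p < alpha; the scheme
    controls false discovery by intersection, not by per-gene
    adjustment.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    s_hybrid = _lookup(contrasts, STERILE_CONTRASTS[0]).significant(alpha)
    s_mxm = _lookup(contrasts, STERILE_CONTRASTS[1]).significant(alpha)
    s_dxd = _lookup(contrasts, STERILE_CONTRASTS[2]).significant(alpha)
    if mode == "hybrid_and_one_parent":
        genes = s_hybrid & (s_mxm | s_dxd)
    else:
        genes = s_hybrid & s_mxm & s_dxd
        if mode == "all_three_clean":
            for name in FERTILE_CONTRASTS:
                genes -= _lookup(contrasts, name).significant(alpha)
    return SterilitySet(mode=mode, gene_ids=genes)


def bin_direction(matrix: ExpressionMatrix, genes) -> dict[str, str]:
    """Classify each gene by the sterile genotype's mean expression.

    ``higher`` when the MxD mean exceeds each of the three fertile
    genotype means, ``lower`` when below each, else ``intermediate``
    (exact ties fall in ``intermediate`` — conservative, and of measure
    zero for continuous data).
    """
    genes = list(genes)
    missing = set(genes) - set(matrix.gene_ids)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
    means = matrix.subset_genes(genes).genotype_means()
    for g in (STERILE_GENOTYPE,) + FERTILE_GENOTYPES:
        if g not in means.columns:
            raise ValueError(f"genotype {g} missing from matrix")
    sterile = means[STERILE_GENOTYPE]
    fertile = means[list(FERTILE_GENOTYPES)]
    higher = (sterile > fertile.max(axis=1))
    lower = (sterile < fertile.min(axis=1))
    out: dict[str, str] = {}
    for gene in genes:
        if higher.loc[gene]:
            out[gene] = "higher"
        elif lower.loc[gene]:
            out[gene] = "lower"
        else:
            out[gene] = "intermediate"
    return out


def attach_directions(
    sterility_set: SterilitySet, matrix: ExpressionMatrix
) -> SterilitySet:
    return SterilitySet(
        mode=sterility_set.mode,
        gene_ids=set(sterility_set.gene_ids),
        direction=bin_direction(matrix, sterility_set.gene_ids),
    )


def direction_counts(sterility_set: SterilitySet) -> pd.Series:
    counts = {d: len(sterility_set.members(d)) for d in DIRECTIONS}
    return pd.Series(counts)
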