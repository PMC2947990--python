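"""Core data containers: the expression matrix and the gene annotation table.

Both are thin, validated wrappers around pandas objects so that every
pipeline stage shares one vocabulary:

* ``ExpressionMatrix`` — genes x samples values plus per-sample metadata
  (genotype and replicate).  Values are linear-scale straight after probe
  summarisation and log2-scale after quantile normalisation; the
  ``scale`` attribute records which.
* gene annotations — a plain DataFrame with columns ``gene_id``,
  ``chromosome``, ``position_mb``, ``cell_class``, ``x_class`` (schema
  checked by :func:`validate_annotations`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("DxD", "MxM", "DxM", "MxD")
FERTILE_GENOTYPES = ("DxD", "MxM", "DxM")
STERILE_GENOTYPE = "MxD"

AUTOSOMES = tuple(str(i) for i in range(1, 20))
CHROMOSOMES = AUTOSOMES + ("X", "Y")

CELL_CLASSES = ("somatic", "mitotic", "meiotic", "postmeiotic")
X_CLASSES = ("A", "B", "C", "D", "E")

ANNOTATION_COLUMNS = ("gene_id", "chromosome", "position_mb", "cell_class", "x_class")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample genotype metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample metadata does not match matrix columns")
        missing = set(("genotype", "replicate")) - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
        bad = set(self.sample_meta["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes in sample metadata: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, genotype: str) -> list[str]:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        cols = list(self.sample_meta.index[self.sample_meta["genotype"] == genotype])
        if not cols:
            raise ValueError(f"no samples with genotype {genotype!r}")
        return cols

    def genotype_means(self) -> pd.DataFrame:
        """Per-gene mean expression for each genotype (columns ordered as GENOTYPES)."""
        present = [g for g in GENOTYPES if (self.sample_meta["genotype"] == g).any()]
        return pd.DataFrame(
            {g: self.values[self.samples_of(g)].mean(axis=1) for g in present}
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.sample_meta, self.scale
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.sample_meta.copy(), self.scale
        )


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation schema and its structural invariants.

    Enforces that X-linked genes are never in the meiotic cell class
    (meiotic sex chromosome inactivation makes that combination
    impossible in the study design) and that X-expression classes are
    only assigned to X-linked genes.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    bad_chrom = set(annotations["chromosome"].astype(str)) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValueError(f"unknown chromosomes: {sorted(bad_chrom)}")
    bad_class = set(annotations["cell_class"]) - set(CELL_CLASSES) - {"unassigned"}
    if bad_class:
        raise ValueError(f"unknown cell classes: {sorted(bad_class)}")
    on_x = annotations["chromosome"].astype(str) == "X"
    if (on_x & (annotations["cell_class"] == "meiotic")).any():
        raise ValueError("X-linked genes cannot be in the meiotic cell class")
    has_xclass = annotations["x_class"] != "none"
    if (has_xclass & ~on_x).any():
        raise ValueError("x_class is only defined for X-linked genes")
    bad_x = set(annotations.loc[has_xclass, "x_class"]) - set(X_CLASSES)
    if bad_x:
        raise ValueError(f"unknown x_class values: {sorted(bad_x)}")
    if (annotations["position_mb"] < 0).any():
        raise ValueError("positions must be nonnegative")
    if annotations["gene_id"].duplicated().any():
        raise ValueError("duplicate gene identifiers")
    return annotations


def make_sample_meta(replicates: int = 3) -> pd.DataFrame:
    """The study layout: four genotypes with ``replicates`` males each."""
    rows = [
        (f"{g}_{r}", g, r)
        for g in GENOTYPES
        for r in range(1, replicates + 1)
    ]
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate"])
    return meta.set_index("sample_id")


def annotation_index(annotations: pd.DataFrame) -> pd.DataFrame:
    """Annotations re-indexed by gene_id for fast lookups."""
    return annotations.set_index("gene_id", drop=False)


def is_autosomal(chrom: pd.Series | np.ndarray) -> np.ndarray:
    c = np.asarray(chrom, dtype=str)
    return np.isin(c, AUTOSOMES)
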