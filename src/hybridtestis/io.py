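"""Tab-separated readers and writers for every pipeline artifact.

All tabular I/O is TSV with documented headers; the expression matrix
additionally has a GCT-dialect writer (versioned ``#1.2`` header) and
the annotation table a BED-like export (0-based half-open intervals,
positions in bp) for interoperability with genome-interval tools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix, validate_annotations

PROBE_COLUMNS = ("gene_id", "probe_index", "sample_id", "pm", "mm")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_probe_table(path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise ValueError(f"probe table lacks columns: {sorted(missing)}")
    if (probes[["pm", "mm"]] < 0).any().any():
        raise ValueError("probe intensities must be nonnegative")
    if probes[["pm", "mm"]].isna().any().any():
        raise ValueError("probe intensities must be finite")
    return probes


def write_probe_table(probes: pd.DataFrame, path) -> None:
    write_tsv(probes[list(PROBE_COLUMNS)], path)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return validate_annotations(ann)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    write_tsv(annotations, path)


def write_annotations_bed(annotations: pd.DataFrame, path, feature_bp: int = 1000) -> None:
    """BED6-like export: chrom, start, end, gene_id, score, strand.

    Positions are Mb * 1e6 rounded to integer bp; each gene is written
    as a ``feature_bp``-long placeholder interval.
    """
    start = (annotations["position_mb"] * 1e6).round().astype(int)
    bed = pd.DataFrame(
        {
            "chrom": "chr" + annotations["chromosome"].astype(str),
            "start": start,
            "end": start + feature_bp,
            "name": annotations["gene_id"],
            "score": 0,
            "strand": "+",
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "genotype", "replicate"} - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return meta.set_index("sample_id")


def write_sample_sheet(meta: pd.DataFrame, path) -> None:
    write_tsv(meta.reset_index(), path)


def read_matrix(path, sample_sheet_path, scale: str = "log2") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = read_sample_sheet(sample_sheet_path).loc[values.columns]
    return ExpressionMatrix(values, meta, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    write_tsv(out, path, index=True)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """GCT 1.2 dialect: version line, dimensions, NAME/Description block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_genes, n_samples = matrix.values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        cols = "\t".join(str(c) for c in matrix.sample_ids)
        fh.write(f"NAME\tDescription\t{cols}\n")
        for gene, row in matrix.values.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_dnds(path) -> pd.DataFrame:
    from .divergence import validate_dnds

    return validate_dnds(pd.read_csv(path, sep="\t"))
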