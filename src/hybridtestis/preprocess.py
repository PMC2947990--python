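"""From probe-level PM/MM intensities to the analysis-ready log2 matrix.

Three stages, mirroring a classical Affymetrix workflow:

1. detection calls — a gene is kept only if its perfect-match signal is
   significantly above mismatch (one-sided Wilcoxon signed-rank,
   p < 0.01) in *every* sample;
2. probe summarisation — one robust value per gene per sample (Tukey
   median polish by default; a trimmed mean as alternative).  The exact
   commercial probe-weighting estimator used on the original chips is
   unpublished in detail, so the summariser is a documented, pluggable
   stand-in behind one interface;
3. quantile normalisation followed by log2.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import signed_rank_p_greater

logger = logging.getLogger(__name__)

MIN_PROBES = 5
SUMMARIZERS = ("median_polish", "trimmed_mean")


def _probe_cube(probes: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Per gene: (pm, mm) arrays of shape (n_probes, n_samples) + sample order.

    Requires each gene to carry the same probes in every sample (probe
    tables are per-chip layouts, so this holds for real and simulated
    data alike).
    """
    out = {}
    for gene, grp in probes.groupby("gene_id", sort=True):
        pm = grp.pivot(index="probe_index", columns="sample_id", values="pm")
        mm = grp.pivot(index="probe_index", columns="sample_id", values="mm")
        if pm.isna().any().any() or mm.isna().any().any():
            raise ValueError(f"gene {gene}: probes missing in some samples")
        out[gene] = (pm.to_numpy(float), mm.to_numpy(float), list(pm.columns))
    return out


def detect_and_filter(
    probes: pd.DataFrame,
    alpha: float = 0.01,
    required_samples: int | None = None,
) -> set[str]:
    """Detection calls: retain genes expressed in all samples.

    A gene counts as expressed in a sample when the one-sided Wilcoxon
    signed-rank test of its paired (PM, MM) probe intensities gives
    p < ``alpha``.  By default a gene must be detected in every sample
    present in the table (``required_samples=None``); pass a smaller
    count to relax that.

    Genes with fewer than ``MIN_PROBES`` probes in any sample are
    excluded with a warning — with so few pairs the exact signed-rank
    test cannot reach p < 0.01.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n_samples_total = probes["sample_id"].nunique()
    need = n_samples_total if required_samples is None else required_samples
    retained: set[str] = set()
    for gene, (pm, mm, _) in _probe_cube(probes).items():
        if pm.shape[0] < MIN_PROBES:
            logger.warning(
                "gene %s has %d probes (< %d); excluded from detection",
                gene, pm.shape[0], MIN_PROBES,
            )
            continue
        p = signed_rank_p_greater(pm, mm)
        if (p < alpha).sum() >= need and pm.shape[1] == n_samples_total:
            retained.add(gene)
    return retained


def median_polish(y: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> tuple[float, np.ndarray, np.ndarray]:
    """Tukey's median polish of a probes x samples matrix.

    Returns (overall, row_effects, col_effects); the fitted value for
    sample j is overall + col_effects[j], robust to outlying probes.
    """
    r = np.asarray(y, dtype=float).copy()
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        r -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        overall += cmed_of_row
        row -= cmed_of_row
        cmed = np.median(r, axis=0)
        r -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        overall += rmed_of_col
        col -= rmed_of_col
        if abs(rmed).max(initial=0.0) < tol and abs(cmed).max(initial=0.0) < tol:
            break
    return overall, row, col


def summarize_probes(
    probes: pd.DataFrame,
    retained: Iterable[str],
    method: str = "median_polish",
    trim: float = 0.1,
) -> ExpressionMatrix:
    """One linear-scale expression value per retained gene per sample.

    The probe-level signal is the background-corrected quantity
    ``max(PM - MM, 1)``; the floor keeps the subsequent log2 finite.
    ``median_polish`` fits an additive probe + sample decomposition on
    the log2 scale and reports ``2**(overall + sample effect)``;
    ``trimmed_mean`` averages the middle (1 - 2*trim) of probes on the
    linear scale.
    """
    if method not in SUMMARIZERS:
        raise ValueError(f"unknown summarizer {method!r}; choose from {SUMMARIZERS}")
    retained = set(retained)
    all_genes = set(probes["gene_id"].unique())
    unknown = retained - all_genes
    if unknown:
        raise ValueError(f"retained genes absent from probe table: {sorted(unknown)[:5]}")

    cube = _probe_cube(probes[probes["gene_id"].isin(retained)])
    sample_order: list[str] | None = None
    rows = {}
    for gene, (pm, mm, samples) in cube.items():
        if sample_order is None:
            sample_order = samples
        corrected = np.maximum(pm - mm, 1.0)
        if method == "median_polish":
            overall, _, col = median_polish(np.log2(corrected))
            rows[gene] = 2.0 ** (overall + col)
        else:
            from scipy.stats import trim_mean

            rows[gene] = np.maximum(trim_mean(corrected, trim, axis=0), 1.0)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_order)
    values = values.sort_index()

    meta = _sample_meta_from_ids(values.columns)
    return ExpressionMatrix(values, meta, scale="linear")


def _sample_meta_from_ids(sample_ids) -> pd.DataFrame:
    """Recover (genotype, replicate) from 'GENOTYPE_r' sample identifiers."""
    rows = []
    for sid in sample_ids:
        geno, _, rep = str(sid).rpartition("_")
        rows.append((sid, geno, int(rep) if rep.isdigit() else 0))
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype", "replicate"]
    ).set_index("sample_id")


def quantile_normalize_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise columns to a common distribution, then log2.

    The reference distribution is the across-column mean of the sorted
    values; tied values within a column receive the mean of the
    reference quantiles their ranks span.  Values below 1 are floored at
    1 (with a warning) so the log is finite.  Applying the operation
    twice is a no-op on the log2 output.
    """
    vals = matrix.values.to_numpy(float).copy()
    if (vals <= 0).any():
        logger.warning(
            "%d nonpositive values floored at 1 before normalization",
            int((vals <= 0).sum()),
        )
        vals = np.maximum(vals, 1.0)
    n, m = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(vals)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference values across runs of tied observations
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and col_sorted[stop] == col_sorted[start]:
                stop += 1
            if stop - start > 1:
                assigned[start:stop] = assigned[start:stop].mean()
            start = stop
        out[order[:, j], j] = assigned

    normalized = pd.DataFrame(
        np.log2(np.maximum(out, 1.0)),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(normalized, matrix.sample_meta, scale="log2")


def preprocess_pipeline(
    probes: pd.DataFrame,
    alpha: float = 0.01,
    method: str = "median_polish",
) -> tuple[ExpressionMatrix, set[str]]:
    """detect -> summarize -> quantile-normalise, returning the log2 matrix."""
    retained = detect_and_filter(probes, alpha=alpha)
    if not retained:
        raise ValueError("no genes passed detection")
    linear = summarize_probes(probes, retained, method=method)
    return quantile_normalize_log2(linear), retained
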