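"""Model/results facade tying the pipeline stages together.

``HybridTestisModel`` is built from an analysis-ready log2 expression
matrix and a gene annotation table (or, via :meth:`from_probes`, from
probe-level PM/MM data that is first detected, summarised and
normalised).  ``fit`` runs the full analysis — pairwise contrasts with
exhaustive permutation FDRs, the hierarchical sterility-correlated gene
set with direction bins, chromosome-wise and cell-type enrichment, the
composition-robust gene filter, chromosome deviation profiles and
X-vs-autosome shift tests, plus the optional dN/dS stratum comparison —
and returns a ``HybridTestisResults`` object carrying every table, with
a ``summary()`` in the spirit of statsmodels results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as htio
from .composition import robust_gene_table, robust_genes
from .diffexpr import ContrastResult, FdrEstimate, permutation_fdr, ttest_contrast
from .divergence import DndsComparison, dnds_rank_compare
from .enrichment import (
    XClassBias,
    celltype_enrichment_table,
    chromosome_enrichment,
    xclass_bias,
)
from .matrix import (
    ExpressionMatrix,
    FERTILE_GENOTYPES,
    GENOTYPES,
    STERILE_GENOTYPE,
    annotation_index,
    validate_annotations,
)
from .preprocess import preprocess_pipeline
from .profiles import DeviationProfile, all_pairwise_shifts, chromosome_deviation_profile
from .sterility import (
    STERILE_CONTRASTS,
    SterilitySet,
    attach_directions,
    direction_counts,
    select_sterility_correlated,
)

SPECIES_CONTRAST = ("MxM", "DxD")


class HybridTestisModel:
    """Fertile-vs-sterile hybrid testis expression analysis.

    Parameters
    ----------
    expression : ExpressionMatrix
        Quantile-normalised log2 matrix of the 4 genotypes x replicates.
    annotations : DataFrame
        Per-gene chromosome, position, cell class, X-expression class.
    dnds : DataFrame, optional
        Per-gene dN/dS records for the protein-evolution comparison.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotations: pd.DataFrame,
        dnds: pd.DataFrame | None = None,
        dnds_annotations: pd.DataFrame | None = None,
    ) -> None:
        if expression.scale != "log2":
            raise ValueError("expression must be on the log2 scale (normalise first)")
        self.expression = expression
        self.annotations = validate_annotations(annotations)
        ann_ids = set(self.annotations["gene_id"])
        missing = set(expression.gene_ids) - ann_ids
        if missing:
            raise ValueError(
                f"{len(missing)} matrix genes lack annotation, e.g. {sorted(missing)[:3]}"
            )
        self.dnds = dnds
        self.dnds_annotations = dnds_annotations if dnds_annotations is not None else annotations

    @classmethod
    def from_probes(
        cls,
        probes: pd.DataFrame,
        annotations: pd.DataFrame,
        detection_alpha: float = 0.01,
        summarizer: str = "median_polish",
        **kwargs,
    ) -> "HybridTestisModel":
        """Build the model from probe-level PM/MM data.

        Runs detection calls (p < ``detection_alpha`` in all samples),
        probe summarisation and quantile normalisation, then keeps only
        detected genes.
        """
        normalized, retained = preprocess_pipeline(
            probes, alpha=detection_alpha, method=summarizer
        )
        ann = annotations[annotations["gene_id"].isin(retained)].reset_index(drop=True)
        return cls(normalized, ann, **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        set_mode: str = "hybrid_and_one_parent",
        fdr_alpha: float = 0.05,
    ) -> "HybridTestisResults":
        """Run every analysis stage and collect the results."""
        expr = self.expression
        present = [g for g in GENOTYPES if (expr.sample_meta["genotype"] == g).any()]
        contrasts: dict[str, ContrastResult] = {}
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                c = ttest_contrast(expr, a, b)
                contrasts[c.contrast_name] = c

        fdrs: dict[str, FdrEstimate] = {}
        watched = set(STERILE_CONTRASTS) | {f"{SPECIES_CONTRAST[0]}_vs_{SPECIES_CONTRAST[1]}"}
        for name in contrasts:
            a, _, b = name.partition("_vs_")
            flipped = f"{b}_vs_{a}"
            if name in watched or flipped in watched:
                fdrs[name] = permutation_fdr(expr, a, b, alpha=alpha)

        sterility = select_sterility_correlated(contrasts, mode=set_mode, alpha=alpha)
        sterility = attach_directions(sterility, expr)

        universe = set(expr.gene_ids)
        chrom_enrich_sterility = chromosome_enrichment(
            sterility.gene_ids, universe, self.annotations
        )
        species_set = set()
        for c in contrasts.values():
            if {c.group_a, c.group_b} == set(SPECIES_CONTRAST):
                species_set = c.significant(alpha)
                break
        chrom_enrich_species = (
            chromosome_enrichment(species_set, universe, self.annotations)
            if species_set
            else None
        )

        panels = {
            "all": sterility.gene_ids,
            "higher": sterility.members("higher"),
            "lower": sterility.members("lower"),
            "intermediate": sterility.members("intermediate"),
        }
        celltype_table = celltype_enrichment_table(panels, universe, self.annotations)

        robust = robust_genes(sterility, self.annotations)
        robust_table = robust_gene_table(robust, sterility, self.annotations)

        profile = chromosome_deviation_profile(expr, self.annotations)
        shifts = all_pairwise_shifts(expr, self.annotations)
        xbias = xclass_bias(expr, self.annotations) if "X" in set(
            self.annotations["chromosome"].astype(str)
        ) else None

        dnds_result = None
        if self.dnds is not None:
            dnds_result = dnds_rank_compare(self.dnds, self.dnds_annotations)

        return HybridTestisResults(
            model=self,
            alpha=alpha,
            set_mode=set_mode,
            fdr_alpha=fdr_alpha,
            contrasts=contrasts,
            fdr_estimates=fdrs,
            sterility_set=sterility,
            chromosome_enrichment_sterility=chrom_enrich_sterility,
            chromosome_enrichment_species=chrom_enrich_species,
            celltype_enrichment=celltype_table,
            robust_genes=robust,
            robust_gene_table=robust_table,
            deviation_profile=profile,
            shift_tests=shifts,
            xclass_bias=xbias,
            dnds=dnds_result,
        )


@dataclass
class HybridTestisResults:
    """Container for every fitted table, with a text ``summary()``."""

    model: HybridTestisModel
    alpha: float
    set_mode: str
    fdr_alpha: float
    contrasts: dict[str, ContrastResult]
    fdr_estimates: dict[str, FdrEstimate]
    sterility_set: SterilitySet
    chromosome_enrichment_sterility: pd.DataFrame
    chromosome_enrichment_species: pd.DataFrame | None
    celltype_enrichment: pd.DataFrame
    robust_genes: set[str]
    robust_gene_table: pd.DataFrame
    deviation_profile: DeviationProfile
    shift_tests: pd.DataFrame
    xclass_bias: XClassBias | None
    dnds: DndsComparison | None

    def x_deviation_percent(self, genotype: str = STERILE_GENOTYPE) -> float:
        """Back-transformed mean X-chromosome deviation of a genotype."""
        return self.deviation_profile.percent(genotype, "X")

    def summary(self) -> str:
        lines = []
        add = lines.append
        expr = self.model.expression
        add("Hybrid testis expression analysis")
        add("=" * 60)
        add(f"genes: {len(expr.gene_ids)}   samples: {len(expr.sample_ids)}")
        add(f"per-contrast alpha: {self.alpha}   set mode: {self.set_mode}")
        add("")
        add("Pairwise contrasts (significant genes, permutation FDR)")
        for name, c in sorted(self.contrasts.items()):
            n_sig = c.n_significant(self.alpha)
            fdr = self.fdr_estimates.get(name)
            fdr_txt = (
                f"{fdr.fdr:.3f}" if fdr is not None and fdr.defined
                else ("undefined" if fdr is not None else "-")
            )
            add(f"  {name:14s} n_sig={n_sig:5d}  FDR={fdr_txt}")
        add("")
        counts = direction_counts(self.sterility_set)
        add(
            f"Sterility-correlated genes ({self.set_mode}): "
            f"{len(self.sterility_set.gene_ids)} "
            f"[higher {counts['higher']}, lower {counts['lower']}, "
            f"intermediate {counts['intermediate']}]"
        )
        x_row = self.chromosome_enrichment_sterility.query("chromosome == 'X'")
        if not x_row.empty:
            add(
                "X-chromosome representation: "
                f"{int(x_row['observed'].iloc[0])} observed vs "
                f"{x_row['expected'].iloc[0]:.1f} expected "
                f"(corrected p = {x_row['p_corrected'].iloc[0]:.2g})"
            )
        add(f"Composition-robust genes: {len(self.robust_genes)}")
        try:
            pct = self.x_deviation_percent()
            add(f"Mean X deviation in {STERILE_GENOTYPE}: {pct:+.1f}%")
        except KeyError:
            pass
        if self.dnds is not None:
            s = self.dnds.summary
            add(
                "dN/dS X vs autosomes: "
                f"medians {s.loc['X', 'median']:.3f} vs "
                f"{s.loc['autosomes', 'median']:.3f}, p = {self.dnds.p_value:.2g}"
            )
        return "\n".join(lines)

    def to_dir(self, out_dir) -> None:
        """Write every result table as TSV under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, c in self.contrasts.items():
            t = c.table.copy()
            t.index.name = "gene_id"
            htio.write_tsv(t, out / f"contrast_{name}.tsv", index=True)
        fdr_rows = [
            (e.contrast_name, e.alpha, e.n_observed_significant,
             e.fdr if e.defined else "NA",
             ",".join(str(c) for c in e.permutation_counts))
            for e in self.fdr_estimates.values()
        ]
        htio.write_tsv(
            pd.DataFrame(
                fdr_rows,
                columns=["contrast", "alpha", "n_observed", "fdr", "permutation_counts"],
            ),
            out / "fdr_estimates.tsv",
        )
        sset = pd.DataFrame(
            sorted(
                (g, self.sterility_set.mode, self.sterility_set.direction[g])
                for g in self.sterility_set.gene_ids
            ),
            columns=["gene_id", "mode", "direction"],
        )
        htio.write_tsv(sset, out / "sterility_set.tsv")
        htio.write_tsv(
            self.chromosome_enrichment_sterility, out / "chromosome_enrichment_sterility.tsv"
        )
        if self.chromosome_enrichment_species is not None:
            htio.write_tsv(
                self.chromosome_enrichment_species, out / "chromosome_enrichment_species.tsv"
            )
        htio.write_tsv(self.celltype_enrichment, out / "celltype_enrichment.tsv")
        htio.write_tsv(self.robust_gene_table, out / "robust_genes.tsv")
        htio.write_tsv(
            self.deviation_profile.chromosome_table, out / "deviation_profile.tsv"
        )
        htio.write_tsv(self.shift_tests, out / "shift_tests.tsv")
        if self.xclass_bias is not None:
            htio.write_tsv(self.xclass_bias.table, out / "xclass_bias.tsv")
        if self.dnds is not None:
            s = self.dnds.summary.copy()
            s.index.name = "stratum"
            s["p_value"] = self.dnds.p_value
            htio.write_tsv(s, out / "dnds_comparison.tsv", index=True)
        (out / "summary.txt").write_text(self.summary() + "\n")
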