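"""Synthetic testis-expression generator with an explicit cell-type mixture.

Whole testis is a mixture of four spermatogenic cell populations
(somatic/Sertoli, mitotic spermatogonia, meiotic spermatocytes,
postmeiotic round spermatids).  The generator models the tissue-level
signal of gene *g* in a sample of genotype *t* as

    S_{g,s} = ( sum_c f_c(t) * a_{g,c} )
              * 2^(delta_g * s(t)) * 2^(beta * [t = MxD and g on X])
              * 2^(eps_{g,s}),     eps ~ Normal(0, sigma^2)

where ``f_c(t)`` are the genotype's tissue cell-type fractions,
``a_{g,c}`` is the per-cell activity of the gene (maximal in its own
cell class, a small configurable leakage elsewhere), ``delta_g`` is a
species-divergence effect carried by a random subset of genes (enriched
among meiotic genes), ``s(t)`` scores the Mus musculus genome dose of
the genotype (-1/2 for DxD, +1/2 for MxM, 0 for the F1 hybrids), and
``beta`` is the X-chromosome over-expression implanted only in the
sterile MxD genotype.  Probe-level perfect-match / mismatch intensities
are layered on top so the detection-call and summarisation stages have
realistic input.

Sterile MxD males lose most postmeiotic cells; their default cell
fractions shift mass from the postmeiotic to the earlier compartments,
which is exactly the confound the cellular-composition model downstream
is designed to expose.

``null_mode`` switches every systematic effect off (delta = beta = 0,
identical cell fractions in all genotypes), giving exchangeable samples
for calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import (
    AUTOSOMES,
    CELL_CLASSES,
    CHROMOSOMES,
    GENOTYPES,
    STERILE_GENOTYPE,
    X_CLASSES,
    make_sample_meta,
    validate_annotations,
)

# Approximate mouse chromosome lengths (GRCm38, Mb), used only to place
# genes at plausible coordinates.
CHROM_LENGTH_MB = {
    "1": 195.5, "2": 182.1, "3": 160.0, "4": 156.5, "5": 151.8,
    "6": 149.7, "7": 145.4, "8": 129.4, "9": 124.6, "10": 130.7,
    "11": 122.1, "12": 120.1, "13": 120.4, "14": 124.9, "15": 104.0,
    "16": 98.2, "17": 95.0, "18": 90.7, "19": 61.4, "X": 171.0, "Y": 91.7,
}

# Mus musculus genome dose per genotype: parents are pure species, the
# reciprocal F1 hybrids carry one genome of each.
SPECIES_SCORE = {"DxD": -0.5, "MxM": 0.5, "DxM": 0.0, "MxD": 0.0}


def _default_chrom_weights() -> dict[str, float]:
    """X share matches the ~3% of the detected-gene universe implied by the
    study's chromosome-wise expectations; autosomes scale with length."""
    x_w, y_w = 0.0303, 0.001
    total_auto = sum(CHROM_LENGTH_MB[c] for c in AUTOSOMES)
    w = {c: (1.0 - x_w - y_w) * CHROM_LENGTH_MB[c] / total_auto for c in AUTOSOMES}
    w["X"] = x_w
    w["Y"] = y_w
    return w


# Cell-class mixes of the detected universe, per stratum.  The autosomal
# mix is the class composition of assignable autosomal genes; on the X
# the meiotic class is empty (MSCI) and the mitotic class is inflated.
DEFAULT_CELLCLASS_AUTOSOME = (0.1236, 0.3169, 0.3366, 0.2229)
DEFAULT_CELLCLASS_X = (0.1797, 0.5435, 0.0, 0.2768)

# Fertile testis is dominated by postmeiotic cells (~85% of cells);
# the sterile hybrid loses most of them, the remainder re-scaling up.
DEFAULT_CELL_FRACTIONS = {
    "DxD": (0.02, 0.08, 0.05, 0.85),
    "MxM": (0.02, 0.08, 0.05, 0.85),
    "DxM": (0.02, 0.08, 0.05, 0.85),
    "MxD": (0.06, 0.24, 0.15, 0.55),
}


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with study-scale defaults."""

    n_genes: int = 7000
    chrom_weights: dict[str, float] = field(default_factory=_default_chrom_weights)
    cellclass_weights_autosome: tuple[float, ...] = DEFAULT_CELLCLASS_AUTOSOME
    cellclass_weights_X: tuple[float, ...] = DEFAULT_CELLCLASS_X
    unassigned_prob: float = 0.33
    xclass_weights: tuple[float, ...] = (0.35, 0.28, 0.15, 0.12, 0.10)
    cell_fractions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CELL_FRACTIONS)
    )
    leakage: float = 0.05
    divergence_prob: float = 0.10
    divergence_effect_log2: float = 0.5
    divergence_meiotic_multiplier: float = 3.0
    x_overexpression_log2: float = math.log2(1.17)
    noise_sd_log2: float = 0.15
    n_probes_per_gene: int = 17
    mm_cross_fraction: float = 0.35
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    affinity_sd_log2: float = 0.5
    background_median: float = 50.0
    background_sd_log2: float = 0.5
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        tol = 1e-9
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_probes_per_gene < 1:
            raise ValueError("n_probes_per_gene must be >= 1")
        if abs(sum(self.chrom_weights.values()) - 1.0) > tol:
            raise ValueError("chromosome weights must sum to 1")
        unknown = set(self.chrom_weights) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosomes in weights: {sorted(unknown)}")
        for name, w in (
            ("cellclass_weights_autosome", self.cellclass_weights_autosome),
            ("cellclass_weights_X", self.cellclass_weights_X),
            ("xclass_weights", self.xclass_weights),
        ):
            if any(v < 0 for v in w):
                raise ValueError(f"{name} has negative entries")
            if abs(sum(w) - 1.0) > tol:
                raise ValueError(f"{name} must sum to 1")
        if self.cellclass_weights_X[CELL_CLASSES.index("meiotic")] != 0.0:
            raise ValueError("meiotic weight on the X chromosome must be exactly 0")
        if set(self.cell_fractions) != set(GENOTYPES):
            raise ValueError(f"cell_fractions must cover genotypes {GENOTYPES}")
        for g, f in self.cell_fractions.items():
            if len(f) != 4 or any(v < 0 for v in f):
                raise ValueError(f"cell fractions for {g} must be a nonnegative 4-vector")
            if abs(sum(f) - 1.0) > tol:
                raise ValueError(f"cell fractions for {g} must sum to 1")
        if not 0.0 <= self.unassigned_prob < 1.0:
            raise ValueError("unassigned_prob must lie in [0, 1)")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named RNG sub-streams derived from the one root seed.

        Each generative stage draws from its own child stream, so e.g.
        changing the probe count does not perturb the annotation draws.
        """
        root = np.random.SeedSequence(self.seed)
        names = ("annotations", "base", "divergence", "noise",
                 "affinity", "background", "dnds")
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The exchangeable-null version of a configuration: no divergence,
    no X implant, identical cell fractions in every genotype."""
    fertile = config.cell_fractions["DxD"]
    return replace(
        config,
        divergence_prob=0.0,
        x_overexpression_log2=0.0,
        cell_fractions={g: tuple(fertile) for g in GENOTYPES},
    )


def generate_annotations(config: SimulationConfig) -> pd.DataFrame:
    """Draw a seeded gene annotation table following the configured weights."""
    rng = config.streams()["annotations"]
    chroms = list(config.chrom_weights)
    probs = np.array([config.chrom_weights[c] for c in chroms])
    chrom = rng.choice(chroms, size=config.n_genes, p=probs)
    pos = rng.uniform(0.0, 1.0, size=config.n_genes) * np.array(
        [CHROM_LENGTH_MB[c] for c in chrom]
    )

    on_x_like = np.isin(chrom, ("X", "Y"))  # Y is silenced in meiosis too
    w_auto = np.asarray(config.cellclass_weights_autosome)
    w_x = np.asarray(config.cellclass_weights_X)
    unassigned = rng.uniform(size=config.n_genes) < config.unassigned_prob
    draw_auto = rng.choice(len(CELL_CLASSES), size=config.n_genes, p=w_auto)
    draw_x = rng.choice(len(CELL_CLASSES), size=config.n_genes, p=w_x)
    cls_idx = np.where(on_x_like, draw_x, draw_auto)
    cell_class = np.array([CELL_CLASSES[i] for i in cls_idx], dtype=object)
    cell_class[unassigned] = "unassigned"

    x_class = np.full(config.n_genes, "none", dtype=object)
    is_x = chrom == "X"
    x_class[is_x] = rng.choice(
        X_CLASSES, size=int(is_x.sum()), p=np.asarray(config.xclass_weights)
    )

    width = len(str(config.n_genes))
    ann = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)],
            "chromosome": chrom.astype(str),
            "position_mb": pos,
            "cell_class": cell_class,
            "x_class": x_class,
        }
    )
    return validate_annotations(ann)


def cell_activity(config: SimulationConfig, annotations: pd.DataFrame,
                  base_log2: np.ndarray) -> np.ndarray:
    """Per-cell activity matrix a_{g,c}, shape (n_genes, 4).

    A gene's own cell class carries the full activity; the other classes
    carry ``leakage`` times it — the cell-class labels mean "greatest
    induction", not exclusive expression.  Genes without a class label
    are spread evenly over the four compartments, which makes them
    composition-neutral by construction.

    Activities are normalised per gene so that the *fertile* whole-tissue
    mixture equals ``2**base_log2``: base abundance is defined at the
    tissue level, where the detected-gene universe lives, rather than
    per cell.  Between-genotype fold changes depend only on activity
    ratios, so the normalisation leaves every composition effect intact
    while keeping detectability independent of cell class.
    """
    base = 2.0 ** np.asarray(base_log2)
    n = len(annotations)
    act = np.full((n, 4), config.leakage)
    classes = annotations["cell_class"].to_numpy()
    for ci, cname in enumerate(CELL_CLASSES):
        act[classes == cname, ci] = 1.0
    act[classes == "unassigned", :] = 0.25
    fertile = np.asarray(config.cell_fractions["DxD"])
    act /= (act @ fertile)[:, None]
    return act * base[:, None]


def _true_signal(
    config: SimulationConfig,
    annotations: pd.DataFrame,
    activity: np.ndarray,
    delta: np.ndarray,
    noise: np.ndarray,
    sample_meta: pd.DataFrame,
) -> np.ndarray:
    """Tissue-level linear signal, shape (n_genes, n_samples)."""
    beta = config.x_overexpression_log2
    on_x = (annotations["chromosome"] == "X").to_numpy()
    signals = np.empty((len(annotations), len(sample_meta)))
    for j, sid in enumerate(sample_meta.index):
        t = sample_meta.loc[sid, "genotype"]
        f = np.asarray(config.cell_fractions[t])
        mix = activity @ f
        log2_effect = delta * SPECIES_SCORE[t] + noise[:, j]
        if t == STERILE_GENOTYPE and beta != 0.0:
            log2_effect = log2_effect + beta * on_x
        signals[:, j] = mix * 2.0**log2_effect
    return signals


def generate_dataset(
    config: SimulationConfig,
    annotations: pd.DataFrame,
    null_mode: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate probe-level PM/MM data and the implanted-truth record.

    Returns
    -------
    probes : DataFrame
        Long format with columns gene_id, probe_index, sample_id,
        pm, mm.
    truth : DataFrame
        Per gene: whether it carries a species-divergence effect, the
        signed effect size, and whether the X over-expression implant
        applies to it.
    """
    if len(annotations) != config.n_genes:
        raise ValueError("annotations were not generated from this config")
    cfg = null_config(config) if null_mode else config
    streams = cfg.streams()

    base_log2 = streams["base"].normal(
        cfg.base_log2_mean, cfg.base_log2_sd, size=cfg.n_genes
    )
    activity = cell_activity(cfg, annotations, base_log2)

    rng_div = streams["divergence"]
    p_div = np.full(cfg.n_genes, cfg.divergence_prob)
    meiotic = (annotations["cell_class"] == "meiotic").to_numpy()
    p_div[meiotic] = np.minimum(1.0, p_div[meiotic] * cfg.divergence_meiotic_multiplier)
    divergent = rng_div.uniform(size=cfg.n_genes) < p_div
    signs = rng_div.choice([-1.0, 1.0], size=cfg.n_genes)
    delta = np.where(divergent, signs * cfg.divergence_effect_log2, 0.0)

    sample_meta = make_sample_meta(cfg.replicates)
    noise = streams["noise"].normal(
        0.0, cfg.noise_sd_log2, size=(cfg.n_genes, len(sample_meta))
    )
    signal = _true_signal(cfg, annotations, activity, delta, noise, sample_meta)

    n_probes = cfg.n_probes_per_gene
    affinity = 2.0 ** streams["affinity"].normal(
        0.0, cfg.affinity_sd_log2, size=(cfg.n_genes, n_probes)
    )
    rng_bg = streams["background"]
    shape = (cfg.n_genes, n_probes, len(sample_meta))
    bg_pm = cfg.background_median * 2.0 ** rng_bg.normal(0.0, cfg.background_sd_log2, shape)
    bg_mm = cfg.background_median * 2.0 ** rng_bg.normal(0.0, cfg.background_sd_log2, shape)

    probe_signal = signal[:, None, :] * affinity[:, :, None]
    pm = probe_signal + bg_pm
    mm = cfg.mm_cross_fraction * probe_signal + bg_mm

    g_idx, p_idx, s_idx = np.meshgrid(
        np.arange(cfg.n_genes), np.arange(n_probes), np.arange(len(sample_meta)),
        indexing="ij",
    )
    gene_ids = annotations["gene_id"].to_numpy()
    sample_ids = sample_meta.index.to_numpy()
    probes = pd.DataFrame(
        {
            "gene_id": gene_ids[g_idx.ravel()],
            "probe_index": p_idx.ravel(),
            "sample_id": sample_ids[s_idx.ravel()],
            "pm": pm.ravel(),
            "mm": mm.ravel(),
        }
    )

    on_x = (annotations["chromosome"] == "X").to_numpy()
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "divergent": divergent,
            "divergence_log2": delta,
            "x_overexpressed": on_x & (cfg.x_overexpression_log2 != 0.0),
            "base_log2": base_log2,
        }
    )
    return probes, truth


def tissue_signal_matrix(
    config: SimulationConfig,
    annotations: pd.DataFrame,
    null_mode: bool = False,
) -> pd.DataFrame:
    """Noise-inclusive tissue-level signal without the probe layer.

    Convenience for tests and fast simulations that exercise only the
    matrix-level stages; identical mixture, divergence, implant and
    noise draws as :func:`generate_dataset` (same sub-streams).
    """
    cfg = null_config(config) if null_mode else config
    streams = cfg.streams()
    base_log2 = streams["base"].normal(cfg.base_log2_mean, cfg.base_log2_sd, cfg.n_genes)
    activity = cell_activity(cfg, annotations, base_log2)
    rng_div = streams["divergence"]
    p_div = np.full(cfg.n_genes, cfg.divergence_prob)
    meiotic = (annotations["cell_class"] == "meiotic").to_numpy()
    p_div[meiotic] = np.minimum(1.0, p_div[meiotic] * cfg.divergence_meiotic_multiplier)
    divergent = rng_div.uniform(size=cfg.n_genes) < p_div
    signs = rng_div.choice([-1.0, 1.0], size=cfg.n_genes)
    delta = np.where(divergent, signs * cfg.divergence_effect_log2, 0.0)
    sample_meta = make_sample_meta(cfg.replicates)
    noise = streams["noise"].normal(0.0, cfg.noise_sd_log2, (cfg.n_genes, len(sample_meta)))
    signal = _true_signal(cfg, annotations, activity, delta, noise, sample_meta)
    return pd.DataFrame(signal, index=annotations["gene_id"].to_numpy(),
                        columns=sample_meta.index)


def simulate_dnds(
    n_x: int = 152,
    n_autosome: int = 5611,
    median_x: float = 0.160,
    median_autosome: float = 0.112,
    sigma_log: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic dN/dS table with log-normal rate ratios per stratum.

    Defaults mirror the study's reported stratum sizes and medians for
    X-linked versus autosomal testis-expressed genes.  Returns the
    records table and a minimal matching annotation table.
    """
    rng = np.random.default_rng(seed)
    n = n_x + n_autosome
    chrom = np.array(["X"] * n_x + ["1"] * n_autosome, dtype=object)
    med = np.where(chrom == "X", median_x, median_autosome)
    dnds = med * np.exp(rng.normal(0.0, sigma_log, size=n))
    ds = 10.0 ** rng.uniform(-1.0, 0.0, size=n)
    gene_ids = [f"d{i:05d}" for i in range(1, n + 1)]
    records = pd.DataFrame(
        {"gene_id": gene_ids, "dn": dnds * ds, "ds": ds, "dnds": dnds}
    )
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chrom.astype(str),
            "position_mb": 0.0,
            "cell_class": "unassigned",
            "x_class": "none",
        }
    )
    return records, validate_annotations(ann)
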