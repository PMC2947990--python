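import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hybridtestis as ht
from hybridtestis.matrix import GENOTYPES, ExpressionMatrix, make_sample_meta
from hybridtestis.simulate import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

EQUAL_FRACTIONS = {g: (0.02, 0.08, 0.05, 0.85) for g in GENOTYPES}


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(n_genes=300, n_probes_per_gene=9, seed=0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def matrix_from_genotype_means(gene_means: dict[str, tuple[float, float, float, float]],
                               jitter: float = 0.0, seed: int = 0) -> ExpressionMatrix:
    """Build a 12-sample log2 matrix with exact genotype means per gene.

    ``gene_means[gene]`` gives the mean for (DxD, MxM, DxM, MxD); an
    optional mean-preserving jitter spreads replicates around it.
    """
    rng = np.random.default_rng(seed)
    meta = make_sample_meta(3)
    rows = {}
    for gene, means in gene_means.items():
        vals = []
        for g in GENOTYPES:
            mu = means[GENOTYPES.index(g)]
            if jitter > 0:
                eps = rng.normal(0, jitter, 3)
                eps -= eps.mean()
            else:
                eps = np.zeros(3)
            vals.extend(mu + eps)
        rows[gene] = vals
    values = pd.DataFrame.from_dict(rows, orient="index", columns=meta.index)
    return ExpressionMatrix(values, meta, scale="log2")


@pytest.fixture(scope="session")
def small_pipeline():
    """A full probe-to-results run on a small default-structure dataset."""
    cfg = small_config(n_genes=500, seed=11)
    ann = ht.generate_annotations(cfg)
    probes, truth = ht.generate_dataset(cfg, ann)
    matrix, retained = ht.preprocess_pipeline(probes)
    ra = ann[ann.gene_id.isin(retained)].reset_index(drop=True)
    model = ht.HybridTestisModel(matrix, ra)
    results = model.fit()
    return dict(config=cfg, annotations=ann, retained_annotations=ra,
                probes=probes, truth=truth, matrix=matrix,
                model=model, results=results)
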