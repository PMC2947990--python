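"""The cellular-composition confound model.

Sterile hybrid testes lose most postmeiotic cells, so a fixed amount of
whole-tissue RNA over-samples the remaining (earlier) cell types: genes
induced in mitotic cells *appear* over-expressed and postmeiotic genes
appear under-expressed even when per-cell transcription is unchanged.
This module encodes the qualitative predictions of that model, the
arithmetic of the mixture worked example, and the filter for genes whose
observed direction contradicts the prediction — the only
sterility-correlated genes not explained by composition alone.
"""

from __future__ import annotations

import logging

import pandas as pd

from .matrix import CELL_CLASSES, annotation_index
from .sterility import SterilitySet

logger = logging.getLogger(__name__)

# Predicted apparent direction in sterile tissue per cell class.  The
# model constrains only the mitotic and postmeiotic compartments;
# somatic and meiotic classes are left unconstrained (sterile males
# retain meiotic cells, and the model makes no statement about them).
DEFAULT_PREDICTION: dict[str, str] = {
    "somatic": "unconstrained",
    "mitotic": "higher",
    "meiotic": "unconstrained",
    "postmeiotic": "lower",
}

_CONTRADICTION = {"higher": "lower", "lower": "higher"}


def composition_fold(
    postmeiotic_fraction_fertile: float,
    postmeiotic_fraction_sterile: float,
) -> tuple[float, float]:
    """Worked example of the mixture arithmetic.

    Given the postmeiotic cell fraction in fertile and sterile testis,
    returns the sterile non-postmeiotic share (percent) and the fold
    increase in relative abundance of non-postmeiotic transcripts:
    e.g. a drop from 85% to 55% postmeiotic means the non-postmeiotic
    share rises from 15% to 45% — a three-fold increase.
    """
    for f in (postmeiotic_fraction_fertile, postmeiotic_fraction_sterile):
        if not 0.0 <= f < 1.0:
            raise ValueError("postmeiotic fractions must lie in [0, 1)")
    non_sterile = 1.0 - postmeiotic_fraction_sterile
    non_fertile = 1.0 - postmeiotic_fraction_fertile
    return 100.0 * non_sterile, non_sterile / non_fertile


def predicted_direction(cell_class: str,
                        prediction: dict[str, str] | None = None) -> str:
    pred = DEFAULT_PREDICTION if prediction is None else prediction
    if cell_class not in CELL_CLASSES:
        raise ValueError(f"unknown cell class {cell_class!r}")
    return pred.get(cell_class, "unconstrained")


def robust_genes(
    sterility_set: SterilitySet,
    annotations: pd.DataFrame,
    prediction: dict[str, str] | None = None,
) -> set[str]:
    """Members whose observed direction contradicts the composition model.

    Only postmeiotic genes binned ``higher`` in the sterile genotype and
    mitotic genes binned ``lower`` contradict the confound and can
    reflect genuine per-cell expression change; everything consistent
    with (or unconstrained by) the model is dropped.  Genes without a
    cell-class label cannot be evaluated and are excluded with a log
    message.
    """
    if not sterility_set.gene_ids:
        return set()
    if not sterility_set.direction:
        raise ValueError("sterility set has no direction bins attached")
    pred = DEFAULT_PREDICTION if prediction is None else prediction
    ann = annotation_index(annotations)
    missing = sterility_set.gene_ids - set(ann.index)
    if missing:
        raise ValueError(f"set members lack annotation: {sorted(missing)[:5]}")
    out: set[str] = set()
    n_unassigned = 0
    for gene in sterility_set.gene_ids:
        cls = ann.loc[gene, "cell_class"]
        if cls not in CELL_CLASSES:
            n_unassigned += 1
            continue
        expected = pred.get(cls, "unconstrained")
        if expected == "unconstrained":
            continue
        if sterility_set.direction[gene] == _CONTRADICTION[expected]:
            out.add(gene)
    if n_unassigned:
        logger.info(
            "%d set members without cell-class label excluded from the "
            "composition filter", n_unassigned,
        )
    return out


def robust_gene_table(
    robust: set[str], sterility_set: SterilitySet, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Reportable table of composition-robust genes."""
    ann = annotation_index(annotations)
    rows = [
        (g, str(ann.loc[g, "chromosome"]), ann.loc[g, "cell_class"],
         sterility_set.direction[g], float(ann.loc[g, "position_mb"]))
        for g in sorted(robust)
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "cell_class", "direction", "position_mb"]
    )
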