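"""Transcribed published cell-type enrichment tables.

These two fixtures transcribe the study's cell-type composition tables:
``table1`` stratifies species-divergent genes (panels: all genes,
higher in M. domesticus, higher in M. musculus) and ``table2``
stratifies sterility-correlated genes (panels: all, higher / lower /
intermediate in the sterile MxD genotype).  Columns: panel, stratum
(autosomes or X), cell_class, observed count, expected count under the
stratified universe mix, and the published Bonferroni-corrected p.
``p_printed`` values of 0.0001 transcribe "<0.0001" bounds; no meiotic
rows exist on the X (meiotic sex chromosome inactivation).

They serve as calibration inputs for the enrichment conventions and as
printed-arithmetic targets; they are not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import CELL_CLASSES


def _load(name: str) -> pd.DataFrame:
    with resources.files("hybridtestis.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    return _load("table1.tsv")


def load_table2() -> pd.DataFrame:
    return _load("table2.tsv")


def universe_class_counts(table: pd.DataFrame, stratum: str) -> pd.Series:
    """Expected counts of the all-genes panel for a stratum.

    These are proportional to the expressed-universe cell-class mix the
    published expectations were derived from, so ratios of them recover
    the universe base proportions exactly.
    """
    sub = table[(table["panel"] == "all") & (table["stratum"] == stratum)]
    out = sub.set_index("cell_class")["expected"]
    return out.reindex([c for c in CELL_CLASSES if c in out.index])


def panel_observed_total(table: pd.DataFrame, panel: str, stratum: str) -> int:
    sub = table[(table["panel"] == panel) & (table["stratum"] == stratum)]
    return int(sub["observed"].sum())
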