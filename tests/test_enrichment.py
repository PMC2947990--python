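"""Chromosome and cell-type enrichment against printed-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hybridtestis.enrichment import (
    celltype_binomial,
    celltype_enrichment_table,
    celltype_expected,
    chromosome_enrichment,
    xclass_bias,
)
from hybridtestis.matrix import make_sample_meta, ExpressionMatrix
from hybridtestis.tables import (
    load_table1,
    load_table2,
    panel_observed_total,
    universe_class_counts,
)

from conftest import matrix_from_genotype_means


def toy_annotations(chroms: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(chroms),
            "chromosome": [chroms[g] for g in chroms],
            "position_mb": 1.0,
            "cell_class": "unassigned",
            "x_class": "none",
        }
    )


class TestChromosomeEnrichment:
    def test_saturated_set_gives_expected_and_p_one(self):
        chroms = {f"g{i}": ("X" if i < 10 else "1") for i in range(100)}
        ann = toy_annotations(chroms)
        universe = set(chroms)
        t = chromosome_enrichment(universe, universe, ann)
        assert np.allclose(t["observed"], t["expected"])
        assert (t["p_corrected"] == 1.0).all()

    def test_toy_counts_match_brute_force_hypergeometric(self):
        chroms = {f"g{i}": ("X" if i < 10 else "1") for i in range(100)}
        ann = toy_annotations(chroms)
        universe = set(chroms)
        gene_set = {f"g{i}" for i in range(9)} | {f"g{i}" for i in range(50, 61)}
        t = chromosome_enrichment(gene_set, universe, ann).set_index("chromosome")
        pmf = sps.hypergeom.pmf(np.arange(11), 100, 10, 20)
        brute = min(1.0, 2 * min(pmf[: 9 + 1].sum(), pmf[9:].sum()))
        family = 2
        assert t.loc["X", "observed"] == 9
        assert t.loc["X", "expected"] == pytest.approx(20 * 10 / 100)
        assert t.loc["X", "p_corrected"] == pytest.approx(
            min(1.0, brute * family), abs=1e-12
        )

    def test_study_scale_expected_count(self):
        # universe of 6998 with 212 X-linked genes; a 902-gene set expects
        # 27.3 on the X
        rng = np.random.default_rng(0)
        chroms = {f"g{i:05d}": ("X" if i < 212 else "1") for i in range(6998)}
        ann = toy_annotations(chroms)
        gene_set = set(list(chroms)[:81]) | {f"g{i:05d}" for i in range(300, 1121)}
        t = chromosome_enrichment(gene_set, set(chroms), ann).set_index("chromosome")
        assert t.loc["X", "expected"] == pytest.approx(27.3, abs=0.05)
        assert t.loc["X", "observed"] == 81
        assert t.loc["X", "p_corrected"] < 1e-4

    def test_set_outside_universe_rejected(self):
        ann = toy_annotations({"a": "1", "b": "2"})
        with pytest.raises(ValueError):
            chromosome_enrichment({"zzz"}, {"a", "b"}, ann)


class TestCelltypeExpected:
    def test_table2_higher_panel_autosomes(self):
        table2 = load_table2()
        base = universe_class_counts(table2, "autosomes")
        total = panel_observed_total(table2, "higher", "autosomes")
        assert total == 34 + 151 + 6 + 4
        expected = celltype_expected(base, total, "autosomes")
        assert expected["mitotic"] == pytest.approx(61.8, abs=0.05)

    def test_table2_higher_panel_x(self):
        table2 = load_table2()
        base = universe_class_counts(table2, "X")
        total = panel_observed_total(table2, "higher", "X")
        assert total == 8 + 25 + 32
        expected = celltype_expected(base, total, "X")
        assert expected["postmeiotic"] == pytest.approx(18.0, abs=0.05)

    def test_zero_panel_total_gives_zero_expected(self):
        e = celltype_expected({"somatic": 5, "mitotic": 5}, 0)
        assert (e == 0).all()

    def test_zero_universe_errors(self):
        with pytest.raises(ValueError):
            celltype_expected({"somatic": 0}, 10)


class TestCelltypeBinomial:
    def test_at_expectation_capped_at_one(self):
        p = celltype_binomial(25, 100, 0.25, family_size=7)
        assert p == 1.0

    def test_monotone_in_family_size(self):
        ps = [celltype_binomial(40, 100, 0.25, family_size=f) for f in (1, 2, 4, 7)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            celltype_binomial(5, 10, 1.2, family_size=1)

    def test_observed_above_total_rejected(self):
        with pytest.raises(ValueError):
            celltype_binomial(11, 10, 0.5, family_size=1)

    @pytest.mark.parametrize(
        "obs,total,num,den,family,printed,tol",
        [
            # calibration cells reproduced from the published tables
            (26, 69, 37.5, 69.0, 3, 0.0222, 0.0015),
            (25, 65, 35.3, 65.0, 3, 0.0369, 0.0025),
            (184, 538, 170.5, 538.1, 4, 0.8445, 0.01),
            (31, 314, 38.8, 314.0, 4, 0.7937, 0.01),
            (55, 538, 66.5, 538.1, 4, 0.5964, 0.01),
            (5, 17, 3.0, 16.9, 3, 0.6300, 0.02),
            (6, 17, 9.2, 16.9, 3, 0.4345, 0.02),
        ],
    )
    def test_reproduces_printed_table_pvalues(self, obs, total, num, den, family,
                                              printed, tol):
        p = celltype_binomial(obs, total, num / den, family_size=family)
        assert p == pytest.approx(printed, abs=tol)


class TestCelltypeTable:
    def test_structure_and_x_has_no_meiotic_rows(self, small_pipeline):
        res = small_pipeline["results"]
        t = res.celltype_enrichment
        assert set(t["stratum"]) <= {"autosomes", "X"}
        x_rows = t[t["stratum"] == "X"]
        if not x_rows.empty:
            assert "meiotic" not in set(x_rows["cell_class"])
            assert (x_rows["family_size"] <= 3).all()
        auto = t[t["stratum"] == "autosomes"]
        assert (auto["family_size"] == 4).all()
        # within a panel/stratum, expected counts sum to the panel total
        for (_, _), grp in t.groupby(["panel", "stratum"]):
            assert grp["expected"].sum() == pytest.approx(grp["panel_total"].iloc[0])


def xclass_matrix(n_per_class: int, shift: float, seed: int = 0):
    """Matrix + annotations with X genes in classes A,B,C,E and a known
    MxD-vs-MxM shift."""
    rng = np.random.default_rng(seed)
    means = {}
    rows = []
    for ci, cls in enumerate(("A", "B", "C", "E")):
        for i in range(n_per_class):
            mu = rng.normal(8, 1)
            means[f"x_{cls}{i}"] = (mu, mu, mu, mu + shift + rng.normal(0, 0.05))
            rows.append((f"x_{cls}{i}", "X", 1.0, "unassigned", cls))
    for i in range(n_per_class * 4):
        mu = rng.normal(8, 1)
        means[f"a_{i}"] = (mu, mu, mu, mu + rng.normal(0, 0.05))
        rows.append((f"a_{i}", "1", 1.0, "unassigned", "none"))
    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_mb",
                                      "cell_class", "x_class"])
    return matrix_from_genotype_means(means, jitter=0.02, seed=seed), ann


class TestXClassBias:
    def test_implanted_shift_detected(self):
        m, ann = xclass_matrix(30, shift=0.4, seed=1)
        res = xclass_bias(m, ann)
        t = res.table.set_index("category")
        assert t.loc["pooled_X", "n"] == 120
        assert t.loc["pooled_X", "prop_higher"] > 0.9
        assert t.loc["pooled_X", "p_value"] < 1e-4
        assert t.loc["autosomes", "p_value"] > 0.01

    def test_null_proportion_near_half(self):
        props = []
        for seed in range(5):
            m, ann = xclass_matrix(40, shift=0.0, seed=seed)
            t = xclass_bias(m, ann).table.set_index("category")
            props.append(t.loc["pooled_X", "prop_higher"])
        assert abs(np.mean(props) - 0.5) < 3 * np.sqrt(0.25 / (160 * 5))

    def test_class_d_excluded(self):
        m, ann = xclass_matrix(10, shift=0.3)
        ann = ann.copy()
        ann.loc[ann["gene_id"] == "x_A0", "x_class"] = "D"
        t = xclass_bias(m, ann).table.set_index("category")
        assert "D" not in t.index
        assert t.loc["pooled_X", "n"] == 39

    def test_balanced_split_gives_p_one(self):
        # 90 of 180 higher: exact balance, two-sided p = 1
        assert sps.binomtest(90, 180, 0.5).pvalue == pytest.approx(1.0)


class TestCrossTableConsistency:
    def test_base_proportions_agree_between_published_tables(self):
        t1, t2 = load_table1(), load_table2()
        for stratum in ("autosomes", "X"):
            b1 = universe_class_counts(t1, stratum)
            b2 = universe_class_counts(t2, stratum)
            p1 = (b1 / b1.sum()).reindex(b2.index)
            p2 = b2 / b2.sum()
            assert np.allclose(p1, p2, atol=0.005)
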