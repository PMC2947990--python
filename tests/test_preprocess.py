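"""Detection calls, probe summarisation and quantile normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from hybridtestis.matrix import ExpressionMatrix, make_sample_meta
from hybridtestis.preprocess import (
    detect_and_filter,
    median_polish,
    quantile_normalize_log2,
    summarize_probes,
)

SAMPLES = [f"{g}_{r}" for g in ("DxD", "MxM", "DxM", "MxD") for r in (1, 2, 3)]


def probe_table(gene_data: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Build a long probe table; gene_data maps gene -> (pm, mm) arrays of
    shape (n_probes, 12)."""
    rows = []
    for gene, (pm, mm) in gene_data.items():
        for p in range(pm.shape[0]):
            for s, sid in enumerate(SAMPLES):
                rows.append((gene, p, sid, pm[p, s], mm[p, s]))
    return pd.DataFrame(rows, columns=["gene_id", "probe_index", "sample_id", "pm", "mm"])


class TestDetection:
    def test_all_pm_above_mm_retained(self):
        # 17 probes, PM > MM everywhere: exact one-sided p = 2^-17 < 0.01
        rng = np.random.default_rng(0)
        mm = rng.lognormal(4, 0.3, (17, 12))
        pm = mm + rng.lognormal(4, 0.3, (17, 12))
        retained = detect_and_filter(probe_table({"gA": (pm, mm)}), alpha=0.01)
        assert retained == {"gA"}

    def test_pm_equal_mm_excluded(self):
        pm = np.full((17, 12), 100.0)
        retained = detect_and_filter(probe_table({"gB": (pm, pm.copy())}), alpha=0.01)
        assert retained == set()

    def test_significant_in_eleven_of_twelve_excluded(self):
        rng = np.random.default_rng(1)
        mm = rng.lognormal(4, 0.3, (17, 12))
        pm = mm + rng.lognormal(4, 0.3, (17, 12))
        pm[:, 5] = mm[:, 5]  # kill the signal in one sample
        retained = detect_and_filter(probe_table({"gC": (pm, mm)}), alpha=0.01)
        assert retained == set()

    def test_too_few_probes_excluded_with_warning(self, caplog):
        pm = np.full((4, 12), 200.0)
        mm = np.full((4, 12), 50.0)
        with caplog.at_level("WARNING"):
            retained = detect_and_filter(probe_table({"gD": (pm, mm)}), alpha=0.01)
        assert retained == set()
        assert "probes" in caplog.text

    def test_alpha_validated(self):
        pm = np.full((6, 12), 100.0)
        with pytest.raises(ValueError):
            detect_and_filter(probe_table({"g": (pm, pm)}), alpha=1.5)

    def test_decisions_match_scalar_scipy(self):
        """Per-sample calls agree with scipy's exact signed-rank test."""
        rng = np.random.default_rng(2)
        mm = rng.lognormal(4, 0.4, (9, 12))
        pm = mm + rng.normal(30, 40, (9, 12))
        table = probe_table({"gE": (pm, mm)})
        retained = detect_and_filter(table, alpha=0.05)
        ref_all = all(
            sps.wilcoxon(pm[:, j], mm[:, j], alternative="greater").pvalue < 0.05
            for j in range(12)
        )
        assert ("gE" in retained) == ref_all


class TestSummarize:
    def test_constant_probes_return_that_value(self):
        pm = np.full((7, 12), 356.0)
        mm = np.full((7, 12), 100.0)
        table = probe_table({"g1": (pm, mm)})
        for method in ("median_polish", "trimmed_mean"):
            m = summarize_probes(table, {"g1"}, method=method)
            assert m.scale == "linear"
            assert np.allclose(m.values.loc["g1"], 256.0)

    def test_outlier_probe_barely_moves_median_polish(self):
        rng = np.random.default_rng(3)
        mm = np.full((17, 12), 50.0)
        pm = mm + rng.lognormal(7, 0.2, (17, 12))
        clean = summarize_probes(probe_table({"g": (pm, mm)}), {"g"}).values.loc["g"]
        pm_out = pm.copy()
        pm_out[0, :] *= 100.0
        dirty = summarize_probes(probe_table({"g": (pm_out, mm)}), {"g"}).values.loc["g"]
        assert np.all(np.abs(dirty / clean - 1.0) < 0.05)
        # a plain mean moves far more: the robustness is real, not slack
        mean_shift = np.abs((pm_out - 50).mean(0) / (pm - 50).mean(0) - 1.0)
        assert np.all(mean_shift > 0.5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        mm = np.full((9, 12), 20.0)
        pm = mm + rng.lognormal(6, 0.3, (9, 12))
        k = 3.7
        pm_scaled = mm + (pm - mm) * k
        base = summarize_probes(probe_table({"g": (pm, mm)}), {"g"}).values.loc["g"]
        scaled = summarize_probes(probe_table({"g": (pm_scaled, mm)}), {"g"}).values.loc["g"]
        assert np.allclose(scaled / base, k, rtol=1e-9)

    def test_unknown_retained_gene_rejected(self):
        pm = np.full((6, 12), 100.0)
        table = probe_table({"g": (pm, pm)})
        with pytest.raises(ValueError, match="absent"):
            summarize_probes(table, {"nope"})

    def test_median_polish_additive_exact(self):
        # exactly additive matrix: the per-sample fit recovers the column
        # effects up to the shared constant absorbed from the row medians
        row = np.array([0.0, 1.0, -1.0, 2.0])
        col = np.array([0.0, 0.5, -0.5])
        y = 5.0 + row[:, None] + col[None, :]
        overall, r, c = median_polish(y)
        fitted = overall + c
        assert np.allclose(fitted - fitted.mean(), col - col.mean(), atol=1e-9)
        assert np.allclose(y - (overall + r[:, None] + c[None, :]), 0.0, atol=1e-9)


def _linear_matrix(values: np.ndarray, columns=None) -> ExpressionMatrix:
    columns = columns or SAMPLES[: values.shape[1]]
    meta = make_sample_meta(3).loc[columns]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                     columns=columns),
        meta, scale="linear",
    )


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        m = _linear_matrix(vals, columns=["DxD_1", "DxD_2"])
        out = quantile_normalize_log2(m)
        expected = np.log2([1.5, 3.0, 4.5])
        assert np.allclose(out.values["DxD_1"], expected)
        assert np.allclose(out.values["DxD_2"], expected)

    def test_identical_columns_become_log2_input(self):
        col = np.array([4.0, 16.0, 2.0, 256.0])
        vals = np.tile(col[:, None], (1, 3))
        m = _linear_matrix(vals, columns=["DxD_1", "DxD_2", "DxD_3"])
        out = quantile_normalize_log2(m)
        for c in out.values:
            assert np.allclose(out.values[c], np.log2(col))

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(6, 1, (50, 12))
        m = _linear_matrix(vals)
        once = quantile_normalize_log2(m)
        twice = quantile_normalize_log2(
            ExpressionMatrix(2.0**once.values, once.sample_meta, scale="linear")
        )
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_columns_share_identical_multiset(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(6, 1, (40, 12))
        out = quantile_normalize_log2(_linear_matrix(vals))
        ref = np.sort(out.values.iloc[:, 0].to_numpy())
        for c in out.values:
            assert np.allclose(np.sort(out.values[c].to_numpy()), ref)

    def test_ties_get_mean_of_tied_reference_quantiles(self):
        vals = np.array([[1.0, 1.0], [1.0, 4.0], [5.0, 9.0]])
        out = quantile_normalize_log2(_linear_matrix(vals, columns=["DxD_1", "DxD_2"]))
        ref = np.sort(vals, axis=0).mean(axis=1)  # (1, 2.5, 7)
        # column 1 has a two-way tie at rank 1-2: both get mean(1, 2.5)
        assert np.allclose(
            2.0 ** out.values["DxD_1"].to_numpy(), [1.75, 1.75, 7.0]
        )
        assert np.allclose(2.0 ** out.values["DxD_2"].to_numpy(), ref)

    def test_nonpositive_values_floored_with_warning(self, caplog):
        vals = np.array([[0.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with caplog.at_level("WARNING"):
            out = quantile_normalize_log2(
                _linear_matrix(vals, columns=["DxD_1", "DxD_2"])
            )
        assert "floored" in caplog.text
        assert np.isfinite(out.values.to_numpy()).all()

    @given(st.integers(0, 2**32 - 1))
    def test_rank_order_preserved_within_columns(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(5, 1, (20, 4))
        out = quantile_normalize_log2(
            _linear_matrix(vals, columns=["DxD_1", "DxD_2", "DxD_3", "MxM_1"])
        )
        for j, c in enumerate(out.values):
            before = sps.rankdata(vals[:, j])
            after = sps.rankdata(out.values[c].to_numpy())
            # QN is monotone: equal ranks up to tie merging
            assert (np.sign(np.subtract.outer(before, before))
                    * np.sign(np.subtract.outer(after, after)) >= 0).all()
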