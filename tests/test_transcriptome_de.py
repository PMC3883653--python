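"""Normalization, differential testing, DE filtering and directional overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_oracle
from rapalife.transcriptome_de import (
    DEFilter,
    ExpressionMatrix,
    differential_test,
    filter_de,
    normalize,
    overlap,
    read_series_matrix,
    relative_matrix,
)
from rapalife.synthetic_data import ExpressionDesign, simulate_expression


def make_matrix(values: pd.DataFrame, groups=None, log2_scale=True):
    meta = pd.DataFrame(
        {"group": groups or ["g"] * values.shape[1]}, index=values.columns)
    return ExpressionMatrix(values=values, metadata=meta, log2_scale=log2_scale)


class TestNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        v = pd.DataFrame({"s1": [5.0, 7.0, 6.0], "s2": [5.0, 7.0, 6.0]})
        out = normalize(make_matrix(v))
        pd.testing.assert_frame_equal(out.values, v)

    def test_two_column_row_means_example(self):
        v = pd.DataFrame({"s1": [0.0, 1.0, 2.0], "s2": [2.0, 3.0, 4.0]})
        out = normalize(make_matrix(v))
        expected = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(out.values, expected)

    def test_columns_share_sorted_values_and_idempotent(self):
        rng = np.random.default_rng(0)
        v = pd.DataFrame(rng.lognormal(2, 1, (50, 6)),
                         columns=[f"s{i}" for i in range(6)])
        out = normalize(make_matrix(v, log2_scale=False))
        cols = [np.sort(out.values[c].to_numpy()) for c in out.values.columns]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0])
        out2 = normalize(out)
        pd.testing.assert_frame_equal(out2.values, out.values)

    def test_ties_get_mean_of_tied_positions(self):
        v = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]})
        out = normalize(make_matrix(v))
        # reference distribution: row means of sorted cols = (1.5, 2.0, 4.5)
        assert out.values["s1"].tolist() == [1.75, 1.75, 4.5]

    def test_non_positive_linear_intensity_names_location(self):
        v = pd.DataFrame({"s1": [1.0, -2.0]}, index=["pA", "pB"])
        meta = pd.DataFrame({"group": ["g"]}, index=["s1"])
        with pytest.raises(ValueError, match="pB"):
            ExpressionMatrix(values=v, metadata=meta, log2_scale=False)


class TestDifferentialTest:
    def test_pooled_t_by_hand(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["p1"],
                         columns=list("abcdef"))
        m = make_matrix(v, groups=["A"] * 3 + ["B"] * 3)
        tab = differential_test(m, list("abc"), list("def"))
        assert tab.loc["p1", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert tab.loc["p1", "p"] == pytest.approx(0.0213, abs=1e-3)

    def test_bh_step_up_enumeration(self):
        np.testing.assert_allclose(
            bh_oracle([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_constant_probe_flagged_with_p_one(self):
        v = pd.DataFrame([[2.0] * 6, [1, 2, 3, 7, 8, 9.0]], index=["flat", "de"],
                         columns=list("abcdef"))
        m = make_matrix(v, groups=["A"] * 3 + ["B"] * 3)
        tab = differential_test(m, list("abc"), list("def"))
        assert tab.loc["flat", "p"] == 1.0
        assert bool(tab.loc["flat", "constant"])
        assert tab.loc["flat", "direction"] == "none"

    def test_percent_change_consistent_with_log2fc(self, small_expression):
        _, intens, meta, _ = small_expression
        m = normalize(ExpressionMatrix(values=intens, metadata=meta))
        tab = differential_test(m, m.samples_in_group("rapa_female"),
                                m.samples_in_group("control_female"))
        np.testing.assert_allclose(
            tab["percent_change"], 100.0 * (np.exp2(tab["log2fc"]) - 1.0))
        assert (tab["adjusted_p"] >= tab["p"] - 1e-12).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=80))
    def test_bh_adjustment_equals_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(np.asarray(pvals), method="fdr_bh")[1]
        np.testing.assert_allclose(adj, bh_oracle(pvals), atol=1e-12)

    def test_overlapping_groups_rejected(self):
        v = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        m = make_matrix(v)
        with pytest.raises(ValueError, match="disjoint"):
            differential_test(m, ["a", "b"], ["b", "c"])


class TestFilterDE:
    @pytest.fixture()
    def contrast(self):
        return pd.DataFrame({
            "log2fc": [1.0, 0.1, np.log2(1.15), -1.0],
            "percent_change": [100.0, 7.2, 15.0, -50.0],
            "p": [0.001, 0.001, 0.001, 0.06],
            "adjusted_p": [0.01, 0.01, 0.05, 0.06],
        }, index=["up_big", "small_change", "edge", "late"])

    def test_strict_inequalities_on_both_criteria(self, contrast):
        out = filter_de(contrast, DEFilter())
        # adjusted p exactly 0.05 and percent change exactly 15 are excluded
        assert list(out.index) == ["up_big"]
        assert out.loc["up_big", "direction"] == "up"

    def test_log2fc_threshold_mode(self, contrast):
        flt = DEFilter(adjusted_p_max=0.05, min_percent_change=None, min_abs_log2fc=0.5)
        out = filter_de(contrast, flt)
        assert list(out.index) == ["up_big"]

    def test_exactly_one_threshold_mode(self):
        with pytest.raises(ValueError):
            DEFilter(min_percent_change=15.0, min_abs_log2fc=1.0)

    def test_planted_counts_match_brute_force_refilter(self, small_expression):
        _, intens, meta, _ = small_expression
        m = normalize(ExpressionMatrix(values=intens, metadata=meta))
        tab = differential_test(m, m.samples_in_group("rapa_female"),
                                m.samples_in_group("control_female"))
        flt = DEFilter()
        out = filter_de(tab, flt)
        brute = tab[(tab["adjusted_p"] < 0.05) & (tab["percent_change"].abs() > 15.0)]
        assert set(out.index) == set(brute.index)


class TestOverlap:
    def test_direction_consistent_counts_and_percentages(self):
        a = pd.DataFrame({"direction": ["up", "up", "down"]}, index=["p1", "p2", "p3"])
        b = pd.DataFrame({"direction": ["up", "down", "down"]}, index=["p1", "p2", "p3"])
        ov = overlap(a, b)
        assert (ov.up_shared, ov.down_shared, ov.total_shared) == (1, 1, 2)
        assert ov.pct_total == pytest.approx(100 * 2 / 3)

    def test_disjoint_lists_share_nothing(self):
        a = pd.DataFrame({"direction": ["up"]}, index=["p1"])
        b = pd.DataFrame({"direction": ["up"]}, index=["p2"])
        ov = overlap(a, b)
        assert ov.total_shared == 0 and ov.pct_total == 0.0


class TestRelativeMatrix:
    def test_reference_columns_average_to_zero(self):
        v = pd.DataFrame({"r1": [1.0, 4.0], "r2": [3.0, 6.0], "t": [5.0, 5.0]})
        m = make_matrix(v, groups=["ref", "ref", "trt"])
        rel = relative_matrix(m, "ref")
        np.testing.assert_allclose(rel[["r1", "r2"]].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(rel["t"], [3.0, 0.0])

    def test_single_sample_reference_becomes_zero(self):
        v = pd.DataFrame({"r": [1.0, 2.0], "t": [2.0, 1.0]})
        m = make_matrix(v, groups=["ref", "trt"])
        rel = relative_matrix(m, "ref")
        np.testing.assert_allclose(rel["r"], 0.0)

    def test_empty_reference_rejected(self):
        v = pd.DataFrame({"t": [1.0]})
        m = make_matrix(v, groups=["trt"])
        with pytest.raises(ValueError, match="empty"):
            relative_matrix(m, "ref")


class TestCalibration:
    def test_null_design_false_positive_rate(self):
        """Zero planted effects: raw p<0.05 rate ~5%, adjusted rate near zero."""
        fracs, adj_fracs = [], []
        for seed in range(5):
            d = ExpressionDesign(n_probes=800, sex_shift=0.0, de_shift=0.0, seed=seed)
            intens, meta, _ = simulate_expression(d)
            m = normalize(ExpressionMatrix(values=intens, metadata=meta))
            tab = differential_test(m, m.samples_in_group("rapa_female"),
                                    m.samples_in_group("control_female"))
            fracs.append((tab["p"] < 0.05).mean())
            adj_fracs.append((tab["adjusted_p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (800 * 5))
        assert abs(np.mean(fracs) - 0.05) < 4 * se
        assert np.mean(adj_fracs) <= 0.05 + 3 * se

    def test_empirical_fdr_with_planted_effects(self):
        """B-H keeps the realized FDR of the joint filter near the nominal 5%.

        Tested on the log2 signal directly: quantile normalization under a
        very strong planted signature adds a small, separate distortion of
        null probes that is not a property of the testing machinery.
        """
        fdrs = []
        for seed in range(8):
            d = ExpressionDesign(n_probes=800, n_sex_genes=12, n_de_genes=150, seed=seed)
            intens, meta, truth = simulate_expression(d)
            m = ExpressionMatrix(values=np.log2(intens), metadata=meta, log2_scale=True)
            tab = differential_test(m, m.samples_in_group("rapa_female"),
                                    m.samples_in_group("control_female"))
            out = filter_de(tab, DEFilter())
            is_true = (truth.de_direction["female_treated"] != 0) | truth.sex_gene
            false_hits = (~is_true.loc[out.index]).sum()
            fdrs.append(false_hits / max(1, len(out)))
        assert np.mean(fdrs) <= 0.075


class TestSeriesMatrixReader:
    def test_reads_table_between_markers(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(
            "!Series_title\t\"demo\"\n"
            "!series_matrix_table_begin\n"
            "ID_REF\tS1\tS2\n"
            "p1\t1.5\t2.5\n"
            "p2\t3.0\t4.0\n"
            "!series_matrix_table_end\n")
        meta = pd.DataFrame({"group": ["a", "b"]}, index=["S1", "S2"])
        m = read_series_matrix(p, meta)
        assert m.values.shape == (2, 2)
        assert m.values.loc["p2", "S2"] == 4.0

    def test_missing_table_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("!Series_title\t\"demo\"\n")
        meta = pd.DataFrame({"group": []})
        with pytest.raises(ValueError, match="table"):
            read_series_matrix(p, meta)
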