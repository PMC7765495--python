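"""Count ingestion, CPM arithmetic, the expression pre-filter and LFC
computation against the time-matched solvent control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from consenseq.preprocess import (CountMatrix, SampleSheet, ValidationError, cpm,
                                  direction_table, filter_low_expression, lfc_vs_control,
                                  read_counts, read_lfc, read_sample_sheet, write_counts,
                                  write_lfc, write_sample_sheet)
from conftest import make_counts, make_sheet


class TestIO:
    def test_round_trip(self, tmp_path):
        cm = CountMatrix(pd.DataFrame([[1, 2], [3, 4]],
                                      index=pd.Index(["g1", "g2"], name="gene_id"),
                                      columns=["s1", "s2"]))
        write_counts(cm, tmp_path / "c.tsv")
        back = read_counts(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)

    def test_sheet_round_trip(self, tmp_path, toy_sheet):
        write_sample_sheet(toy_sheet, tmp_path / "s.tsv")
        back = read_sample_sheet(tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.table, toy_sheet.table)

    def test_sample_mismatch_names_the_sample(self, toy_sheet, toy_counts):
        extra = toy_counts.counts.copy()
        extra["mystery_sample"] = 1
        with pytest.raises(ValidationError, match="mystery_sample"):
            toy_sheet.validate_against(CountMatrix(extra))

    def test_non_integer_counts_rejected(self, tmp_path):
        (tmp_path / "c.tsv").write_text("gene_id\ts1\ns_gene\t3.7\n")
        with pytest.raises(ValidationError, match="integer"):
            read_counts(tmp_path / "c.tsv")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            CountMatrix(pd.DataFrame({"s1": [-1]}, index=["g1"]))

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame({"s1": [1, 2]}, index=["g1", "g1"])
        with pytest.raises(ValidationError, match="duplicate"):
            CountMatrix(df)

    def test_unknown_treatment_rejected(self):
        df = pd.DataFrame({"sample": ["a"], "treatment": ["mock"],
                           "timepoint_h": [3], "replicate": [1]})
        with pytest.raises(ValidationError, match="mock"):
            SampleSheet(df)


class TestCpm:
    def test_arithmetic_identity(self):
        cm = CountMatrix(pd.DataFrame({"s1": [500, 999500]}, index=["g1", "g2"]))
        x = cpm(cm)
        assert x.loc["g1", "s1"] == 500.0

    def test_all_zero_gene(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 10]}, index=["g0", "g1"]))
        assert (cpm(cm).loc["g0"] == 0).all()

    def test_columns_sum_to_million_and_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        cm = CountMatrix(pd.DataFrame(rng.integers(1, 1000, (10, 4)),
                                      index=[f"g{i}" for i in range(10)],
                                      columns=list("abcd")))
        x = cpm(cm)
        assert np.allclose(x.sum(axis=0), 1e6)
        libs = cm.counts.sum(axis=0)
        for g in cm.gene_ids:
            for s in cm.sample_ids:
                assert x.loc[g, s] == pytest.approx(cm.counts.loc[g, s] / libs[s] * 1e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.integers(1, 100, (5, 2)), index=[f"g{i}" for i in range(5)],
                            columns=["a", "b"])
        scaled = base.copy()
        scaled["a"] = scaled["a"] * 7
        x1, x2 = cpm(CountMatrix(base)), cpm(CountMatrix(scaled))
        assert np.allclose(x1["a"], x2["a"])

    def test_zero_library_rejected(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0]}, index=["g1"]))
        with pytest.raises(ValidationError, match="library"):
            cpm(cm)


class TestFilter:
    def test_zero_gene_removed_and_boundary_inclusive(self, toy_sheet):
        n = len(toy_sheet.sample_ids)
        # gene g1 at exactly 1 CPM mean: 1 count in libraries of 1e6 total
        counts = pd.DataFrame(0, index=["g0", "g1", "g2"], columns=toy_sheet.sample_ids)
        counts.loc["g1"] = 1
        counts.loc["g2"] = 999999
        cm = CountMatrix(counts)
        kept = filter_low_expression(cm, min_cpm=1.0)
        assert list(kept.gene_ids) == ["g1", "g2"]

    def test_matches_bruteforce_scan(self, toy_sheet):
        cm = make_counts(toy_sheet, n_genes=50, seed=4, lam=2.0)
        kept = filter_low_expression(cm, toy_sheet, min_cpm=1.0, treatment="SB")
        x = cpm(cm)
        from consenseq.preprocess import experiment_samples
        cols = experiment_samples(toy_sheet, "SB")
        expect = [g for g in cm.gene_ids if x.loc[g, cols].mean() >= 1.0]
        assert list(kept.gene_ids) == expect

    @given(lo=st.floats(min_value=0, max_value=5), hi_extra=st.floats(min_value=0, max_value=5))
    def test_monotone_in_threshold(self, lo, hi_extra):
        sheet = make_sheet()
        cm = make_counts(sheet, n_genes=30, seed=2, lam=3.0)
        a = set(filter_low_expression(cm, min_cpm=lo).gene_ids)
        b = set(filter_low_expression(cm, min_cpm=lo + hi_extra).gene_ids)
        assert b <= a


class TestLfc:
    def _fixed_counts(self, sheet, trt_val, ctl_val):
        counts = pd.DataFrame(0, index=["g0", "filler"], columns=sheet.sample_ids)
        counts.loc["filler"] = 1000
        for s in sheet.samples("SB"):
            counts.loc["g0", s] = trt_val
        for s in sheet.samples("DMSO") + sheet.samples("untreated"):
            counts.loc["g0", s] = ctl_val
        return CountMatrix(counts)

    def test_equal_means_give_zero(self, toy_sheet):
        cm = self._fixed_counts(toy_sheet, 50, 50)
        lfc = lfc_vs_control(cm, toy_sheet, "SB")
        assert np.allclose(lfc.loc["g0"], 0.0)

    def test_hand_arithmetic(self):
        """mean CPM treated 8, DMSO 2, pc 0.5 -> log2(8.5/2.5) = 1.766."""
        sheet = make_sheet()
        counts = pd.DataFrame(0, index=["g0", "filler"], columns=sheet.sample_ids)
        for s in sheet.samples("SB"):
            counts.loc["g0", s] = 8
        for s in sheet.samples("DMSO") + sheet.samples("untreated"):
            counts.loc["g0", s] = 2
        counts.loc["filler"] = [1e6 - v for v in counts.loc["g0"]]
        cm = CountMatrix(counts.astype(int))
        lfc = lfc_vs_control(cm, sheet, "SB", pseudocount=0.5)
        assert lfc.loc["g0", 3] == pytest.approx(np.log2(8.5 / 2.5), abs=1e-9)
        assert np.log2(8.5 / 2.5) == pytest.approx(1.766, abs=5e-4)

    def test_antisymmetry_under_label_swap(self, toy_sheet):
        cm = make_counts(toy_sheet, n_genes=20, seed=3)
        lfc = lfc_vs_control(cm, toy_sheet, "SB")
        swapped = toy_sheet.table.copy().reset_index(drop=True)
        swapped["treatment"] = swapped["treatment"].map(
            {"SB": "DMSO", "DMSO": "SB", "untreated": "untreated"})
        lfc_swapped = lfc_vs_control(cm, SampleSheet(swapped), "SB")
        assert np.allclose(lfc.to_numpy(), -lfc_swapped.to_numpy())

    def test_missing_control_group_is_error(self):
        sheet_df = make_sheet().table.copy().reset_index(drop=True)
        sheet_df = sheet_df[~((sheet_df.treatment == "DMSO") & (sheet_df.timepoint_h == 6))]
        sheet = SampleSheet(sheet_df)
        cm = make_counts(sheet, n_genes=5, seed=0)
        with pytest.raises(ValidationError, match="DMSO"):
            lfc_vs_control(cm, sheet, "SB")

    def test_lfc_table_round_trip_with_directions(self, tmp_path, toy_sheet):
        cm = make_counts(toy_sheet, n_genes=10, seed=6)
        lfc = lfc_vs_control(cm, toy_sheet, "SB")
        write_lfc(lfc, tmp_path / "lfc.tsv", lam=0.5)
        back = read_lfc(tmp_path / "lfc.tsv")
        assert list(back.columns) == [3, 6, 9]
        assert np.allclose(back.to_numpy(), lfc.to_numpy())

    def test_direction_table(self):
        lfc = pd.DataFrame({3: [0.6, -0.7, 0.2]}, index=list("abc"))
        d = direction_table(lfc, lam=0.5)
        assert list(d[3]) == ["up", "down", "none"]
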