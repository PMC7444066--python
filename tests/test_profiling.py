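"""Profiling summaries: histograms, fractions, coverage, TPM."""

import numpy as np
import pandas as pd
import pytest

import tsrnakit as tk
from tsrnakit.classify import TsRNARecord
from tsrnakit.profiling import CountMatrix
from tsrnakit.readproc import AlignmentHit


def record(seq_len, counts, label="i-tRF", start=20):
    seq = "A" * seq_len
    return TsRNARecord(seq, f"tRF-{seq_len}-XX", ["toy"], label,
                       start, start + seq_len, counts)


@pytest.fixture(scope="module")
def pipeline_records(refs, contaminants, small_simulation):
    """Classified records from the shared simulation, both samples."""
    mirna, rrna = contaminants
    profile, reads, _ = small_simulation
    per_sample = {}
    totals = {}
    for sample, sample_reads in reads.items():
        trimmed = tk.length_filter(
            [tk.trim_adapter(r, profile.adapter) for r in sample_reads])
        hits = tk.hierarchical_assign(trimmed, mirna, rrna, refs,
                                      max_mismatch=0)
        trna = [h for h in hits if h.category == "tRNA"]
        per_sample[sample] = tk.collapse_and_count(trna, refs, sample)
        totals[sample] = len(trimmed)
    records = tk.merge_records(per_sample)
    meta = pd.DataFrame(
        {"day": [int(s[1:].split("_")[0]) for s in per_sample],
         "replicate": [1] * len(per_sample)},
        index=pd.Index(per_sample.keys(), name="sample_id"))
    matrix = tk.records_to_matrix(records, meta, pd.Series(totals))
    return records, matrix


class TestLengthHistogram:
    def test_fraction_arithmetic(self):
        records = [record(20, {"s1": 30}), record(33, {"s1": 70})]
        assert tk.length_histogram(records, "s1") == {20: 0.3, 33: 0.7}

    def test_single_record(self):
        assert tk.length_histogram([record(25, {"s1": 4})], "s1") == {25: 1.0}

    def test_empty_sample_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert tk.length_histogram([record(25, {"s1": 4})], "s2") == {}
        assert "no tsRNA reads" in caplog.text

    def test_simulated_lengths_mostly_in_modes(self, pipeline_records):
        records, _ = pipeline_records
        hist = tk.length_histogram(records, "d7_r1")
        assert abs(sum(hist.values()) - 1.0) < 1e-9
        in_modes = sum(frac for length, frac in hist.items()
                       if 17 <= length <= 23 or 30 <= length <= 36)
        assert in_modes >= 0.8


class TestTsrnaFraction:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [1500, 500]}, index=["a", "b"])
        meta = pd.DataFrame({"day": [0], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        matrix = CountMatrix(counts, meta, pd.Series({"s1": 10_000}))
        assert tk.tsrna_fraction(matrix)["s1"] == 0.2

    def test_all_zero_column(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        meta = pd.DataFrame({"day": [0], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        matrix = CountMatrix(counts, meta, pd.Series({"s1": 100}))
        assert tk.tsrna_fraction(matrix)["s1"] == 0.0

    def test_rises_from_day0_to_day7(self, pipeline_records):
        """The generator plants rising tsRNA abundance into day 7."""
        _, matrix = pipeline_records
        fracs = tk.tsrna_fraction(matrix)
        assert fracs["d7_r1"] > fracs["d0_r1"]


class TestClassFractions:
    def test_even_split(self):
        records = [record(20, {"s1": 50}, label="tRF-5"),
                   record(40, {"s1": 50}, label="3p-half")]
        assert tk.class_fractions(records, "s1") == \
            {"tRF-5": 0.5, "3p-half": 0.5}

    def test_all_six_classes_detected_in_simulation(self, pipeline_records):
        records, _ = pipeline_records
        fracs = tk.class_fractions(records, "d7_r1")
        for label in tk.CLASS_LABELS:
            assert fracs.get(label, 0) > 0, label
        assert abs(sum(fracs.values()) - 1.0) < 1e-9

    def test_empty_sample(self):
        assert tk.class_fractions([], "s1") == {}


class TestPositionalCoverage:
    def test_five_prime_fragments_start_at_zero(self, toy_ref):
        hits = [AlignmentHit(f"r{i}", "tRNA", toy_ref.trna_id, 0, 18)
                for i in range(4)]
        records = tk.collapse_and_count(hits, [toy_ref], "s1")
        start_depth, _ = tk.positional_coverage(records, toy_ref)
        assert start_depth[0] == 4
        assert start_depth.sum() == 4

    def test_three_prime_fragments_end_at_cca(self, toy_ref):
        m = toy_ref.trailer_start
        hits = [AlignmentHit("a", "tRNA", toy_ref.trna_id, 40, m),
                AlignmentHit("b", "tRNA", toy_ref.trna_id, 50, m)]
        records = tk.collapse_and_count(hits, [toy_ref], "s1")
        _, end_depth = tk.positional_coverage(records, toy_ref)
        assert end_depth[m - 1] == 2

    def test_empty_records(self, toy_ref):
        start_depth, end_depth = tk.positional_coverage([], toy_ref)
        assert start_depth.sum() == end_depth.sum() == 0
        assert len(start_depth) == len(toy_ref.extended_seq)


class TestTpm:
    def make(self, col, total):
        counts = pd.DataFrame({"s1": col},
                              index=[f"t{i}" for i in range(len(col))])
        meta = pd.DataFrame({"day": [0], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        return CountMatrix(counts, meta, pd.Series({"s1": total}))

    def test_arithmetic(self):
        values = tk.tpm(self.make([5, 15], 20))["s1"]
        assert list(values) == [250_000.0, 750_000.0]

    def test_scale_invariance(self):
        a = tk.tpm(self.make([5, 15], 20))
        b = tk.tpm(self.make([10, 30], 40))
        pd.testing.assert_frame_equal(a, b)

    def test_column_conservation(self, pipeline_records):
        """Each TPM column sums to 1e6 x (mapped tsRNA share)."""
        _, matrix = pipeline_records
        table = tk.tpm(matrix)
        for sample in matrix.sample_ids:
            share = matrix.counts[sample].sum() / matrix.totals[sample]
            assert table[sample].sum() == pytest.approx(1e6 * share)

    def test_zero_total_rejected(self):
        counts = pd.DataFrame({"s1": [0]}, index=["a"])
        meta = pd.DataFrame({"day": [0], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        matrix = CountMatrix(counts, meta, pd.Series({"s1": 0}))
        with pytest.raises(ValueError, match="zero total"):
            tk.tpm(matrix)


class TestCountMatrixValidation:
    def test_totals_below_column_sum_rejected(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        meta = pd.DataFrame({"day": [0], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        with pytest.raises(ValueError, match="totals"):
            CountMatrix(counts, meta, pd.Series({"s1": 5}))

    def test_day_outside_study_requires_override(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        meta = pd.DataFrame({"day": [3], "replicate": [1]},
                            index=pd.Index(["s1"], name="sample_id"))
        with pytest.raises(ValueError, match="timepoints"):
            CountMatrix(counts, meta, pd.Series({"s1": 10}))
        CountMatrix(counts, meta, pd.Series({"s1": 10}), allow_any_days=True)

    def test_tsv_round_trip(self, tmp_path):
        matrix, _ = tk.simulate_count_experiment(20, 2, 3.0, 50.0, 2, seed=1)
        matrix.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.counts, matrix.counts,
                                      check_names=False)
        pd.testing.assert_series_equal(back.totals, matrix.totals,
                                       check_names=False)


def test_plot_profile_writes_figure(tmp_path, pipeline_records):
    records, matrix = pipeline_records
    out = tmp_path / "profile.png"
    tk.profiling.plot_profile(records, matrix, path=out)
    assert out.stat().st_size > 0
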