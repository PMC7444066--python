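"""Synthetic-data generator: determinism, truth consistency, mixtures."""

import io
import math

import numpy as np
import pandas as pd
import pytest

import tsrnakit as tk
from tsrnakit.synth import DEFAULT_CLASS_MIXTURE, PlantedFragment


def fastq_bytes(reads):
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.seq}\n+\nI\n")
    return buf.getvalue()


class TestSimulateReads:
    def test_fixed_seed_byte_identical(self, refs, contaminants):
        mirna, rrna = contaminants
        profile = tk.SimulationProfile(n_reads_per_sample=300, replicates=2,
                                       days=(0, 7), seed=5)
        r1, t1 = tk.simulate_reads(refs, mirna, rrna, profile)
        r2, t2 = tk.simulate_reads(refs, mirna, rrna, profile)
        assert sorted(r1) == sorted(r2)
        for sample in r1:
            assert fastq_bytes(r1[sample]) == fastq_bytes(r2[sample])
        pd.testing.assert_frame_equal(t1, t2)

    def test_all_six_classes_in_truth(self, small_simulation):
        _, _, truth = small_simulation
        trna = truth[truth["category"] == "tRNA"]
        assert set(trna["class_label"]) == set(tk.CLASS_LABELS)

    def test_truth_covers_every_read(self, small_simulation):
        _, reads, truth = small_simulation
        emitted = {r.read_id for sample in reads.values() for r in sample}
        assert emitted == set(truth["read_id"])
        assert len(truth) == len(emitted)

    def test_reads_relocatable_at_stated_interval(self, refs,
                                                  small_simulation):
        profile, reads, truth = small_simulation
        by_id = {r.trna_id: r for r in refs}
        bodies = {r.read_id: r.seq[:len(r.seq) - len(profile.adapter)]
                  for sample in reads.values() for r in sample}
        trna = truth[truth["category"] == "tRNA"]
        for row in trna.itertuples():
            ext = by_id[row.parent_id].extended_seq
            assert ext[row.start:row.end] == bodies[row.read_id]

    def test_adapter_appended_after_body(self, small_simulation):
        profile, reads, truth = small_simulation
        bodies = dict(zip(truth["read_id"], truth["end"] - truth["start"]))
        for sample in reads.values():
            for r in sample[:100]:
                assert r.seq.endswith(profile.adapter)
                if truth.set_index("read_id").loc[r.read_id, "category"] == "tRNA":
                    assert len(r.seq) == bodies[r.read_id] + len(profile.adapter)

    def test_length_modes_hold_majority(self, refs, contaminants):
        mirna, rrna = contaminants
        profile = tk.SimulationProfile(
            n_reads_per_sample=10_000, replicates=1, days=(7,),
            contaminant_fractions={"miRNA": 0.0, "rRNA": 0.0}, seed=21)
        _, truth = tk.simulate_reads(refs, mirna, rrna, profile)
        lens = truth["end"] - truth["start"]
        in_modes = (lens.between(17, 23) | lens.between(30, 36)).mean()
        assert in_modes >= 0.8

    def test_class_mixture_recovered(self, refs, contaminants):
        mirna, rrna = contaminants
        n = 10_000
        profile = tk.SimulationProfile(
            n_reads_per_sample=n, replicates=1, days=(7,),
            contaminant_fractions={"miRNA": 0.0, "rRNA": 0.0}, seed=22)
        _, truth = tk.simulate_reads(refs, mirna, rrna, profile)
        observed = truth["class_label"].value_counts(normalize=True)
        for label, expected in DEFAULT_CLASS_MIXTURE.items():
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed[label] - expected) <= 3 * se, label

    def test_unrealizable_class_rejected_by_name(self, refs, contaminants):
        mirna, rrna = contaminants
        profile = tk.SimulationProfile(
            n_reads_per_sample=10, replicates=1, days=(0,),
            length_modes=((17, 23), (44, 46)), seed=1)
        with pytest.raises(ValueError, match="5p-half"):
            tk.simulate_reads(refs, mirna, rrna, profile)

    def test_planted_fragment_day_profile(self, refs, contaminants):
        mirna, rrna = contaminants
        planted = [PlantedFragment(refs[0].trna_id, "3p-half",
                                   {0: 0.0, 7: 1.0})]
        profile = tk.SimulationProfile(
            n_reads_per_sample=2000, replicates=1, days=(0, 7),
            planted_de=planted, planted_fraction=0.2, seed=9)
        _, truth = tk.simulate_reads(refs, mirna, rrna, profile)
        # the planted fragment is one specific interval; count its reads
        planted_rows = truth[(truth["parent_id"] == refs[0].trna_id)
                             & (truth["class_label"] == "3p-half")]
        top = planted_rows.groupby(["start", "end", "sample_id"]).size()
        day7 = top.xs("d7_r1", level="sample_id").max()
        assert day7 > 50  # strongly represented at day 7

    def test_write_simulation_outputs(self, tmp_path, small_simulation):
        _, reads, truth = small_simulation
        tk.write_simulation(reads, truth, tmp_path)
        for sample in reads:
            assert (tmp_path / f"{sample}.fastq").exists()
        back = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(back) == len(truth)


class TestSimulationProfile:
    def test_yaml_round_trip(self, tmp_path):
        profile = tk.SimulationProfile(
            n_reads_per_sample=123, seed=4,
            planted_de=[PlantedFragment("tRNA-x", "tRF-5", {0: 0.0, 7: 2.0})])
        path = tmp_path / "profile.yaml"
        profile.to_yaml(path)
        assert tk.SimulationProfile.from_yaml(path) == profile

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            tk.SimulationProfile(class_mixture={"tRF-5": 0.9, "tRF-3": 0.3})
        with pytest.raises(ValueError, match="outside"):
            tk.SimulationProfile(contaminant_fractions={"miRNA": 1.4})

    def test_non_integer_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            tk.SimulationProfile(replicates=2.5)


class TestSimulateCountExperiment:
    def test_planted_rows_flagged(self):
        matrix, truth = tk.simulate_count_experiment(
            n_tsrna=300, n_de=6, effect=4.0, base_mean=100.0,
            replicates=3, seed=7)
        assert truth.sum() == 6
        assert matrix.counts.shape == (300, 6)
        assert list(matrix.sample_meta["day"].unique()) == [0, 7]

    def test_no_effect_means_no_de_rows(self):
        _, truth = tk.simulate_count_experiment(
            n_tsrna=50, n_de=5, effect=1.0, base_mean=50.0,
            replicates=3, seed=1)
        assert truth.sum() == 0

    def test_same_seed_identical_matrix(self):
        m1, _ = tk.simulate_count_experiment(100, 3, 2.0, 80.0, 3, seed=5)
        m2, _ = tk.simulate_count_experiment(100, 3, 2.0, 80.0, 3, seed=5)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_absent_then_peak_mode(self):
        matrix, truth = tk.simulate_count_experiment(
            50, 6, 4.0, 100.0, 3, seed=2, mode="absent-then-peak")
        day0 = matrix.samples_for_day(0)
        de_rows = matrix.counts.loc[truth[truth].index]
        assert (de_rows[day0] == 0).all().all()
        day7 = matrix.samples_for_day(7)
        assert (de_rows[day7].mean(axis=1) > 100).all()

    def test_row_ids_are_license_plates(self):
        matrix, _ = tk.simulate_count_experiment(20, 0, 1.0, 50.0, 2, seed=3)
        for plate in matrix.counts.index:
            assert plate.startswith("tRF-")
            tk.decode_license_plate(plate)

    @pytest.mark.parametrize("kwargs", [
        dict(n_tsrna=10, n_de=11, effect=2.0, base_mean=10.0, replicates=3),
        dict(n_tsrna=10, n_de=1, effect=2.0, base_mean=-5.0, replicates=3),
        dict(n_tsrna=10, n_de=1, effect=2.0, base_mean=10.0, replicates=1.5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tk.simulate_count_experiment(seed=0, **kwargs)
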