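import numpy as np
import pandas as pd
import pytest

from gammafoci import (
    GenomeModel,
    GenomicInterval,
    PlantedDomain,
    SyntheticTruth,
    ddct,
    percent_input_table,
    random_truth,
    simulate_chip_qpcr,
    simulate_ct_table,
    simulate_tracks,
    write_fixtures,
)


def truth_with(domains=(), sites=(), rate=10.0, seed=0):
    return SyntheticTruth(tuple(domains), tuple(sites), rate, seed)


class TestSimulateTracks:
    def test_null_model_ratio_near_one(self):
        genome = GenomeModel(("chr1",), (3_000_000,), 150)
        t, c = simulate_tracks(genome, truth_with(rate=10.0, seed=1), library_ratio=1.0)
        ratio = (t.counts["chr1"].mean() / t.total_tags) / (
            c.counts["chr1"].mean() / c.total_tags
        )
        assert ratio == pytest.approx(1.0)
        # raw depth-normalized means agree closely on a 20k-bin genome
        assert t.total_tags / c.total_tags == pytest.approx(1.0, rel=0.01)

    def test_planted_fold_recovered_within_3_se(self):
        genome = GenomeModel(("chr1",), (600_000,), 150)
        dom = PlantedDomain(GenomicInterval("chr1", 0, 300_000), 4.0, "big")
        t, _ = simulate_tracks(genome, truth_with([dom], rate=10.0, seed=2))
        inside = t.counts["chr1"][:2000]  # 2000 replicate bins, mean 40
        se = np.sqrt(40.0 / inside.size)
        assert abs(inside.mean() - 40.0) < 3 * se
        outside = t.counts["chr1"][2000:]
        assert abs(outside.mean() - 10.0) < 3 * np.sqrt(10.0 / outside.size)

    def test_partial_overlap_bin_scales_by_covered_fraction(self):
        genome = GenomeModel(("chr1",), (600_000,), 150)
        # domain covers half of its last bin: [0, 150*1000 + 75)
        dom = PlantedDomain(GenomicInterval("chr1", 0, 150_075), 4.0, "frac")
        means = []
        for seed in range(400):
            t, _ = simulate_tracks(genome, truth_with([dom], rate=10.0, seed=seed))
            means.append(t.counts["chr1"][1000])
        # expected 10 * (1 + 3*0.5) = 25
        assert np.mean(means) == pytest.approx(25.0, abs=3 * np.sqrt(25.0 / 400))

    def test_same_seed_bit_identical(self):
        genome = GenomeModel(("chr1",), (300_000,), 150)
        truth = truth_with(rate=5.0, seed=42)
        t1, c1 = simulate_tracks(genome, truth)
        t2, c2 = simulate_tracks(genome, truth)
        assert np.array_equal(t1.counts["chr1"], t2.counts["chr1"])
        assert np.array_equal(c1.counts["chr1"], c2.counts["chr1"])

    def test_library_ratio_scales_control(self):
        genome = GenomeModel(("chr1",), (3_000_000,), 150)
        _, c = simulate_tracks(genome, truth_with(rate=10.0, seed=3), library_ratio=2.0)
        assert c.counts["chr1"].mean() == pytest.approx(20.0, rel=0.02)

    def test_domain_outside_genome_rejected_by_name(self):
        genome = GenomeModel(("chr1",), (10_000,), 150)
        dom = PlantedDomain(GenomicInterval("chr1", 5_000, 20_000), 2.0, "runaway")
        with pytest.raises(ValueError, match="runaway"):
            simulate_tracks(genome, truth_with([dom]))

    def test_total_equals_sum_of_bins(self):
        genome = GenomeModel(("chr1", "chr2"), (100_000, 50_000), 150)
        t, c = simulate_tracks(genome, truth_with(rate=7.0, seed=4))
        for track in (t, c):
            assert track.total_tags == sum(a.sum() for a in track.counts.values())


class TestSimulateCtTable:
    def test_unit_folds_and_zero_noise_give_unit_estimates(self):
        design = {"ctrl": {"geneA": 1.0}, "trt": {"geneA": 1.0}}
        table = simulate_ct_table(design, ["ref1"], replicates=3, noise_sd=0.0, seed=0)
        res = ddct(table, "geneA", ["ref1"], "ctrl")
        assert all(r.fold_change == pytest.approx(1.0) for r in res)

    def test_fold_four_lowers_ct_by_two_cycles(self):
        design = {"ctrl": {"geneA": 1.0}, "trt": {"geneA": 4.0}}
        table = simulate_ct_table(design, ["ref1"], replicates=2, noise_sd=0.0, seed=0)
        ct = table.groupby(["group", "target"])["ct"].mean()
        assert ct["ctrl", "geneA"] - ct["trt", "geneA"] == pytest.approx(2.0)

    def test_noisy_fold_recovered_within_15_percent(self):
        design = {"ctrl": {"geneA": 1.0}, "trt": {"geneA": 3.0}}
        table = simulate_ct_table(design, ["ref1", "ref2"], replicates=6,
                                  noise_sd=0.2, seed=7)
        res = {r.group: r.fold_change for r in ddct(table, "geneA", ["ref1", "ref2"], "ctrl")}
        assert res["trt"] == pytest.approx(3.0, rel=0.15)

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            simulate_ct_table({"g": {"x": 0.0}}, ["ref"], seed=0)


class TestSimulateChipQpcr:
    def test_noise_free_ct_gap_matches_dilution_identity(self):
        # 1.25% at one-tenth input: Ct_IP - Ct_input = 3 exactly
        table = simulate_chip_qpcr(1.25, input_fraction=0.1, replicates=2,
                                   noise_sd=0.0, seed=0)
        ip = table[table["group"] == "IP"]["ct"].iloc[0]
        inp = table[table["group"] == "input"]["ct"].iloc[0]
        assert ip - inp == pytest.approx(3.0)

    def test_full_input_fraction_and_total_recovery_gives_equal_cts(self):
        table = simulate_chip_qpcr(100.0, input_fraction=1.0, replicates=1,
                                   noise_sd=0.0, seed=0)
        cts = table.set_index("group")["ct"]
        assert cts["IP"] == pytest.approx(cts["input"])

    def test_noisy_percent_recovered_within_10_percent(self):
        table = simulate_chip_qpcr({"locusA": 2.0}, input_fraction=0.1,
                                   replicates=10, noise_sd=0.1, seed=3)
        res = percent_input_table(table, input_fraction=0.1)
        assert res[0].percent_input == pytest.approx(2.0, rel=0.10)


class TestWriteFixtures:
    def _standard(self, tmp_path, seed=0):
        genome = GenomeModel(("chr1",), (60_000,), 150)
        truth = random_truth(genome, n_domains=2, domain_length_range=(2000, 4000),
                             n_sites=3, seed=seed, min_separation=3000)
        t, c = simulate_tracks(genome, truth)
        return write_fixtures(tmp_path, genome, truth, t, c)

    def test_default_config_emits_seven_files(self, tmp_path):
        manifest = self._standard(tmp_path / "a")
        assert len(manifest) == 7
        for entry in manifest:
            assert (tmp_path / "a" / entry["path"]).exists()

    def test_rerun_same_seed_identical_checksums(self, tmp_path):
        m1 = self._standard(tmp_path / "a", seed=5)
        m2 = self._standard(tmp_path / "b", seed=5)
        assert [e["sha256"] for e in m1] == [e["sha256"] for e in m2]

    def test_empty_truth_gives_headers_only_truth_file(self, tmp_path):
        genome = GenomeModel(("chr1",), (30_000,), 150)
        truth = truth_with(rate=10.0, seed=0)
        t, c = simulate_tracks(genome, truth)
        write_fixtures(tmp_path, genome, truth, t, c)
        lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert lines == ["kind\tchrom\tstart\tend\tfold\tlabel"]
        df = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert df.empty


class TestRandomTruth:
    def test_separation_respected(self):
        genome = GenomeModel(("chr1",), (2_000_000,), 150)
        truth = random_truth(genome, n_domains=10, n_sites=10, seed=1,
                             min_separation=20_000)
        ivs = sorted(
            [(d.interval.start, d.interval.end) for d in truth.domains]
            + [(s.interval.start, s.interval.end) for s in truth.sites]
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 - e1 >= 20_000

    def test_reproducible(self):
        genome = GenomeModel(("chr1",), (2_000_000,), 150)
        a = random_truth(genome, seed=9, n_domains=5, n_sites=5)
        b = random_truth(genome, seed=9, n_domains=5, n_sites=5)
        assert a == b
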