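"""Planted-truth generator: distributions, determinism, serialization."""

import numpy as np
import pytest
from scipy import stats

from spikedomains import fragio, synth


class TestMakeTruth:
    def test_uniform_profile_plants_nothing(self, toy_genomes):
        t = synth.make_truth("replication_coupled_uniform", *toy_genomes,
                             seed=1)
        assert len(t.domains) == 0 and len(t.peaks) == 0

    def test_peaky_profile_peak_count(self, toy_genomes):
        t = synth.make_truth("turnover_peaky", *toy_genomes, seed=1,
                             n_peaks=100)
        assert len(t.peaks) == 100

    def test_same_seed_identical_truth(self, toy_genomes):
        a = synth.make_truth("domain_mark", *toy_genomes, seed=5)
        b = synth.make_truth("domain_mark", *toy_genomes, seed=5)
        assert a.domains.df.equals(b.domains.df)
        assert a.peaks == b.peaks

    def test_planted_domains_sorted_non_overlapping(self, toy_genomes):
        t = synth.make_truth("domain_mark", *toy_genomes, seed=8)
        df = t.domains.df
        for _, sub in df.groupby("chrom"):
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_unknown_profile_rejected(self, toy_genomes):
        with pytest.raises(ValueError):
            synth.make_truth("nonsense", *toy_genomes, seed=1)


class TestSimulateSample:
    def test_flat_background_uniformity(self, toy_genomes):
        """Chi-square goodness of fit to uniform over 20 equal windows."""
        primary, spike = toy_genomes
        truth = synth.make_truth("flat_background", primary, spike, seed=2)
        passes = 0
        n_trials = 25
        for seed in range(n_trials):
            frags = synth.simulate_sample(truth, 10_000, seed=seed)
            chr1 = frags.primary[frags.primary["chrom"] == "chr1"]
            counts, _ = np.histogram(chr1["start"], bins=20,
                                     range=(0, primary["chr1"]))
            _, p = stats.chisquare(counts)
            passes += p > 0.01
        assert passes >= int(0.87 * n_trials)

    def test_domain_fragment_fraction_closed_form(self, toy_genomes):
        """One domain at 20x covering 10% of the genome attracts
        20*0.1 / (20*0.1 + 0.9) ~ 69% of primary fragments."""
        primary, spike = toy_genomes
        domains = fragio.regions_from_intervals(
            "d", [("chr1", 0, 1_000_000)])  # 10% of the 10 Mb primary genome
        truth = synth.TruthModel(
            profile="domain_mark", genome=primary, spike_genome=spike,
            domains=domains, domain_multipliers=np.array([20.0]), peaks=[])
        expected = 20 * 0.1 / (20 * 0.1 + 0.9)
        assert truth.domain_fragment_fraction() == pytest.approx(expected,
                                                                 abs=1e-9)
        frags = synth.simulate_sample(truth, 100_000, seed=3)
        inside = ((frags.primary["chrom"] == "chr1")
                  & (frags.primary["start"] < 1_000_000)).mean()
        assert inside == pytest.approx(expected, abs=0.03)

    def test_same_seed_byte_identical_bed(self, toy_genomes, tmp_path):
        primary, spike = toy_genomes
        truth = synth.make_truth("domain_mark", primary, spike, seed=4)
        paths = []
        for i in range(2):
            frags = synth.simulate_sample(truth, 5000, seed=9)
            p = tmp_path / f"f{i}.bed"
            fragio.write_fragment_bed(frags, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_spike_share_within_binomial_error(self, toy_genomes):
        primary, spike = toy_genomes
        truth = synth.make_truth("flat_background", primary, spike, seed=6)
        share = truth.spike_share()
        n = 400_000
        frags = synth.simulate_sample(truth, n, seed=7)
        sd = np.sqrt(share * (1 - share) * n)
        assert abs(frags.spike_count - share * n) < 4 * sd

    def test_fragment_lengths_nucleosomal(self, toy_genomes):
        primary, spike = toy_genomes
        truth = synth.make_truth("flat_background", primary, spike, seed=6)
        frags = synth.simulate_sample(truth, 20_000, seed=8)
        lengths = (frags.primary["end"] - frags.primary["start"]).to_numpy()
        assert lengths.min() >= 50
        assert abs(lengths.mean() - 170) < 2

    def test_replicates_give_concordant_domain_calls(self, toy_genomes):
        """Two seeds over the same truth yield highly overlapping merged
        calls — the premise behind replicate merging."""
        from spikedomains import domains as dom
        from spikedomains import normalize
        primary = fragio.ChromSizes({"chr1": 30_000_000,
                                     "chr2": 30_000_000}, "primary")
        spike = fragio.ChromSizes({"spike1": 3_000_000}, "spike")
        truth = synth.make_truth("domain_mark", primary, spike, seed=40,
                                 n_domains=60, domain_max_len=100_000)
        calls = []
        for seed in (41, 42):
            frags = synth.simulate_sample(truth, 400_000, seed=seed)
            track = normalize.binned_coverage(frags, primary, 100)
            calls.append(dom.call_domains(track, threshold_quantile=0.001))
        inter = 0
        for chrom in primary.chroms:
            a = np.zeros(primary[chrom], dtype=bool)
            b = np.zeros(primary[chrom], dtype=bool)
            for arr, rs in ((a, calls[0]), (b, calls[1])):
                for c, s, e in rs:
                    if c == chrom:
                        arr[s:e] = True
            inter += int((a & b).sum())
        union = calls[0].total_bp + calls[1].total_bp - inter
        assert inter / union > 0.8


class TestTruthReport:
    def test_json_round_trip(self, toy_genomes, tmp_path):
        truth = synth.make_truth("turnover_peaky", *toy_genomes, seed=12,
                                 n_peaks=30)
        back = synth.truth_from_json(synth.truth_to_json(truth))
        assert back.profile == truth.profile
        assert back.peaks == truth.peaks
        assert back.domains.df.equals(truth.domains.df)
        assert back.spike_ratio == truth.spike_ratio

    def test_report_files(self, toy_genomes, tmp_path):
        truth = synth.make_truth("turnover_peaky", *toy_genomes, seed=12,
                                 n_peaks=30)
        dbed, pbed, pjson = (tmp_path / n for n in
                             ("d.bed", "p.bed", "t.json"))
        synth.truth_report(truth, dbed, pbed, pjson)
        assert len(pbed.read_text().splitlines()) == 30
        back = synth.truth_from_json(pjson.read_text())
        assert back.peaks == truth.peaks
        # planted domain BED is valid (sorted, non-overlapping) by contract
        fragio.read_region_bed(dbed)
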