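"""Signal matrices, clustering, and overlap/correlation summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spikedomains import clusterquant as cq
from spikedomains import fragio, normalize, synth


def frag_set(intervals, sample_id="s"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return fragio.FragmentSet(sample_id=sample_id, target="t", primary=df)


class TestSignalMatrix:
    def test_overlap_counting_at_one_bp(self):
        regions = fragio.regions_from_intervals("r", [("chr1", 0, 100)])
        frags = frag_set([("chr1", 50, 150), ("chr1", 200, 300)])
        m = cq.signal_matrix(regions, [(frags, None)], spike_scale=False)
        assert m.values.tolist() == [[1.0]]

    def test_empty_region_list(self):
        regions = fragio.regions_from_intervals("r", [])
        m = cq.signal_matrix(regions, [(frag_set([]), None)],
                             spike_scale=False)
        assert m.values.shape == (0, 1)

    def test_counts_match_brute_force_oracle(self, rng):
        for _ in range(10):
            n_r = int(rng.integers(1, 15))
            cuts = np.sort(rng.choice(100_000, size=2 * n_r, replace=False))
            regions = fragio.regions_from_intervals(
                "r", [("chr1", int(cuts[2 * i]), int(cuts[2 * i + 1]))
                      for i in range(n_r)])
            starts = rng.integers(0, 99_000, size=300)
            frags = frag_set([("chr1", int(s), int(s + rng.integers(50, 900)))
                              for s in starts])
            m = cq.signal_matrix(regions, [(frags, None)], spike_scale=False)
            for i, (c, rs, re_) in enumerate(regions):
                expected = sum(1 for _, fs, fe in frags.primary.itertuples(
                    index=False) if fs < re_ and fe > rs)
                assert m.values[i, 0] == expected

    def test_spike_scaling_applied(self):
        regions = fragio.regions_from_intervals("r", [("chr1", 0, 1000)])
        frags = frag_set([("chr1", 10, 100), ("chr1", 20, 90)])
        scale = normalize.spike_scale_factor(20_000)
        m = cq.signal_matrix(regions, [(frags, scale)])
        assert m.values.tolist() == [[1.0]]


class TestFpkScale:
    def test_arithmetic(self):
        regions = fragio.regions_from_intervals("r", [("chr1", 0, 2000)])
        m = cq.SignalMatrix(regions=regions, samples=["s"],
                            values=np.array([[8.0]]))
        scaled = cq.fpk_scale(m, constants={"s": 0.5})
        assert scaled.values.tolist() == [[2.0]]

    def test_unit_constant_kb_region_is_identity(self):
        regions = fragio.regions_from_intervals("r", [("chr1", 0, 1000)])
        m = cq.SignalMatrix(regions=regions, samples=["s"],
                            values=np.array([[7.0]]))
        assert cq.fpk_scale(m, constants={"s": 1.0}).values.tolist() == [[7.0]]

    def test_double_fpk_rejected(self):
        regions = fragio.regions_from_intervals("r", [("chr1", 0, 1000)])
        m = cq.fpk_scale(cq.SignalMatrix(regions=regions, samples=["s"],
                                         values=np.array([[1.0]])))
        with pytest.raises(ValueError):
            cq.fpk_scale(m)

    def test_fpk_independent_of_region_length_under_uniform_coverage(
            self, toy_genomes):
        primary, spike = toy_genomes
        truth = synth.make_truth("replication_coupled_uniform", primary,
                                 spike, seed=9)
        frags = synth.simulate_sample(truth, 400_000, seed=10)
        lengths = np.linspace(2000, 100_000, 30).astype(int)
        ivs, cursor = [], 0
        for L in lengths:
            ivs.append(("chr1", cursor, cursor + int(L)))
            cursor += int(L) + 1000
        regions = fragio.regions_from_intervals("r", ivs)
        m = cq.fpk_scale(cq.signal_matrix(regions, [(frags, None)],
                                          spike_scale=False))
        fpk = m.values[:, 0]
        slope = np.polyfit(lengths, fpk, 1)[0]
        # FPK is flat in length: slope tiny relative to mean FPK per kb
        assert abs(slope) * np.mean(lengths) < 0.1 * fpk.mean()


class TestKMeans:
    def test_planted_two_cloud_separation(self):
        matrix, labels = synth.planted_matrix(
            n_per_cluster=100, patterns=np.array([[2.0, 9.0], [9.0, 2.0]]),
            noise_sd=0.5, seed=4)
        a = cq.kmeans_cluster(matrix, k=2, seed=0)
        assert adjusted_rand_score(labels, a.labels) == 1.0

    def test_k_equals_rows_zero_withinss(self):
        matrix, _ = synth.planted_matrix(n_per_cluster=2, seed=1)
        n = len(matrix.regions)
        a = cq.kmeans_cluster(matrix, k=n, seed=0)
        assert a.withinss_by_k[n] == pytest.approx(0.0, abs=1e-9)
        assert len(set(a.labels)) == n

    def test_seed_determinism(self):
        matrix, _ = synth.planted_matrix(seed=2)
        a = cq.kmeans_cluster(matrix, k=4, seed=7)
        b = cq.kmeans_cluster(matrix, k=4, seed=7)
        assert (a.labels == b.labels).all()

    def test_more_clusters_than_rows_rejected(self):
        matrix, _ = synth.planted_matrix(n_per_cluster=1, seed=0)
        with pytest.raises(ValueError):
            cq.kmeans_cluster(matrix, k=10, seed=0)


class TestKneeSelection:
    def test_obvious_elbow_curve(self):
        # curve at k = 1..5: sharp elbow entering k = 2
        assert cq.knee_from_curve([1, 2, 3, 4, 5],
                                  [100, 40, 39, 38.5, 38.2]) == 2

    def test_four_planted_clusters_selected(self):
        matrix, _ = synth.planted_matrix(seed=11)
        a = cq.select_k_knee(matrix, seed=11, restarts=10)
        assert a.selected_k == 4

    def test_single_blob_selects_k_min(self):
        picks = []
        for seed in range(10):
            matrix, _ = synth.planted_matrix(
                n_per_cluster=400, patterns=np.array([[5.0, 5.0, 5.0]]),
                noise_sd=0.7, seed=seed)
            picks.append(cq.select_k_knee(matrix, seed=seed,
                                          restarts=10).selected_k)
        assert sorted(picks)[len(picks) // 2] == 2  # modal/median pick

    def test_withinss_non_increasing_in_k(self):
        matrix, _ = synth.planted_matrix(seed=3)
        a = cq.select_k_knee(matrix, seed=3, restarts=10)
        ks = sorted(a.withinss_by_k)
        w = [a.withinss_by_k[k] for k in ks]
        assert all(w[i] >= w[i + 1] - 1e-6 for i in range(len(w) - 1))


class TestOverlapFraction:
    @pytest.mark.parametrize("shared,total,decimals,expected", [
        (5259, 24_733, 1, 21.3),
        (1287, 24_733, 2, 5.20),
        (375, 1401, 1, 26.8),
    ])
    def test_percent_from_printed_counts(self, shared, total, decimals,
                                         expected):
        s = cq.OverlapSummary(shared=shared, total=total, decimals=decimals)
        assert s.percent == expected

    def test_direct_interval_count(self):
        q = fragio.regions_from_intervals("q", [("chr1", 0, 100),
                                                ("chr1", 200, 300)])
        r = fragio.regions_from_intervals("r", [("chr1", 250, 260)])
        s = cq.overlap_fraction(q, r)
        assert (s.shared, s.total, s.percent) == (1, 2, 50.0)

    def test_self_overlap_is_total(self, rng):
        from conftest import random_region_set
        q = random_region_set(rng, "q")
        if len(q) == 0:
            q = fragio.regions_from_intervals("q", [("toyA", 0, 10)])
        assert cq.overlap_fraction(q, q).percent == 100.0

    def test_monotone_in_reference_growth(self):
        q = fragio.regions_from_intervals(
            "q", [("chr1", i * 100, i * 100 + 50) for i in range(10)])
        small = fragio.regions_from_intervals("r", [("chr1", 0, 60)])
        big = fragio.regions_from_intervals(
            "r", [("chr1", 0, 60), ("chr1", 400, 460)])
        assert cq.overlap_fraction(q, big).shared >= \
            cq.overlap_fraction(q, small).shared

    def test_empty_query_undefined(self):
        q = fragio.regions_from_intervals("q", [])
        r = fragio.regions_from_intervals("r", [("chr1", 0, 10)])
        with pytest.raises(ValueError):
            cq.overlap_fraction(q, r)

    def test_round_half_up_at_printed_precision(self):
        assert cq.round_half_up(21.25, 1) == 21.3
        assert cq.round_half_up(5.195, 2) == 5.20
        assert cq.round_half_up(26.84, 1) == 26.8


class TestTssSummaries:
    def test_centered_fragment_gives_symmetric_profile(self):
        frags = frag_set([("chr1", 900, 1100)])
        scale = normalize.spike_scale_factor(10_000)
        m = cq.tss_matrix(frags, scale, [("chr1", 1000)], window=500,
                          bin_width=100)
        row = m.iloc[0].to_numpy()
        np.testing.assert_array_equal(row, row[::-1])

    def test_rows_ordered_by_promoter_signal(self):
        frags = frag_set([("chr1", 900, 1100)] * 3 + [("chr1", 4900, 5100)]
                         + [("chr1", 8900, 9100)] * 2)
        scale = normalize.spike_scale_factor(10_000)
        m = cq.tss_matrix(frags, scale, [("chr1", 1000), ("chr1", 5000),
                                         ("chr1", 9000)], window=500)
        assert list(m.index) == ["chr1:1000", "chr1:9000", "chr1:5000"]

    def test_correlation_identity_and_null(self, rng):
        x = rng.integers(0, 500, size=1000).astype(float)
        assert cq.tss_window_correlation(x, x) == pytest.approx(1.0)
        y = rng.integers(0, 500, size=1000).astype(float)
        assert cq.tss_window_correlation(x, y) < 0.01

    def test_correlation_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cq.tss_window_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            cq.tss_window_correlation([1, 2], [1, 2])

    def test_planted_moderate_coupling_recovered(self, rng):
        """Expression coupled to promoter signal with noise tuned to a
        moderate R² is recovered within ±0.05."""
        n = 2000
        log_sig = rng.normal(5, 1.5, size=n)
        target_r2 = 0.3
        noise_sd = 1.5 * np.sqrt(1 / target_r2 - 1)
        log_expr = log_sig + rng.normal(0, noise_sd, size=n)
        sig = np.maximum(2 ** log_sig - 1, 0)
        expr = np.maximum(2 ** log_expr - 1, 0)
        r2 = cq.tss_window_correlation(sig, expr)
        assert r2 == pytest.approx(target_r2, abs=0.05)


class TestClusterStats:
    def test_textbook_quartiles(self):
        regions = fragio.regions_from_intervals(
            "r", [("chr1", i * 10, i * 10 + 5) for i in range(5)])
        m = cq.SignalMatrix(regions=regions, samples=["s"],
                            values=np.array([[1.0], [2], [3], [4], [5]]))
        a = cq.ClusterAssignment(k=1, labels=np.ones(5, dtype=int),
                                 withinss_by_k={}, selected_k=1, seed=0,
                                 restarts=1)
        stats = cq.cluster_region_stats(m, a)
        row = stats.iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) \
            == (1, 2, 3, 4, 5)

    def test_constant_values_zero_iqr(self):
        regions = fragio.regions_from_intervals(
            "r", [("chr1", i * 10, i * 10 + 5) for i in range(4)])
        m = cq.SignalMatrix(regions=regions, samples=["s"],
                            values=np.full((4, 1), 3.0))
        a = cq.ClusterAssignment(k=1, labels=np.ones(4, dtype=int),
                                 withinss_by_k={}, selected_k=1, seed=0,
                                 restarts=1)
        row = cq.cluster_region_stats(m, a).iloc[0]
        assert row["q3"] - row["q1"] == 0

    def test_matches_reference_quantiles_on_random_data(self, rng):
        vals = rng.random((50, 1)) * 100
        regions = fragio.regions_from_intervals(
            "r", [("chr1", i * 10, i * 10 + 5) for i in range(50)])
        m = cq.SignalMatrix(regions=regions, samples=["s"], values=vals)
        a = cq.ClusterAssignment(k=1, labels=np.ones(50, dtype=int),
                                 withinss_by_k={}, selected_k=1, seed=0,
                                 restarts=1)
        row = cq.cluster_region_stats(m, a).iloc[0]
        np.testing.assert_allclose(
            [row["min"], row["q1"], row["median"], row["q3"], row["max"]],
            np.percentile(vals[:, 0], [0, 25, 50, 75, 100]))
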