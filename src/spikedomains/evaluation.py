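"""Planted-truth benchmarks: run pipeline stages on simulated data and
score them against the ground truth the generator planted.

These are the package's validation workloads — each one builds a seeded
synthetic design, runs the relevant stages end to end, and returns the
recovery metrics (bp Jaccard of domain calls, adjusted Rand index of
cluster structure, fold-change recovery of a planted quantitative
contrast, spike-titration linearity, deposition-regime signatures).
Problem sizes are chosen so each benchmark runs in seconds to a couple of
minutes on one CPU; docs/methods.md records the sizes and why.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import clusterquant as cq
from . import domains, fragio, normalize, pipeline, synth


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _bp_jaccard(a: fragio.RegionSet, b: fragio.RegionSet) -> tuple[int, int, int]:
    """(intersection bp, a bp, b bp) via a sorted two-pointer sweep."""
    inter = 0
    for chrom in set(a.df["chrom"]) | set(b.df["chrom"]):
        A = a.df[a.df["chrom"] == chrom][["start", "end"]].values.tolist()
        B = b.df[b.df["chrom"] == chrom][["start", "end"]].values.tolist()
        i = j = 0
        while i < len(A) and j < len(B):
            s = max(A[i][0], B[j][0])
            e = min(A[i][1], B[j][1])
            if e > s:
                inter += e - s
            if A[i][1] < B[j][1]:
                i += 1
            else:
                j += 1
    return inter, a.total_bp, b.total_bp


def domain_call_recovery(seed: int, n_fragments: int = 1_000_000,
                         n_domains: int = 300,
                         enrichment: float = 20.0) -> dict:
    """Plant broad domains at ``enrichment`` x background on a 2 x 150 Mb
    genome, simulate one sample plus an IgG control, call domains against
    the control, and score base-pair recovery against the planted truth."""
    s = _seeds(seed, 4)
    primary = fragio.ChromSizes({"chr1": 150_000_000,
                                 "chr2": 150_000_000}, "primary")
    spike = fragio.ChromSizes({"spike1": 15_000_000}, "spike")
    truth = synth.make_truth("domain_mark", primary, spike, seed=s[0],
                             n_domains=n_domains, domain_min_len=10_000,
                             domain_max_len=100_000,
                             domain_multiplier=enrichment)
    frags = synth.simulate_sample(truth, n_fragments, seed=s[1])
    track = normalize.binned_coverage(frags, primary, 100)
    igg_truth = synth.make_truth("flat_background", primary, spike, seed=s[2])
    igg = synth.simulate_sample(igg_truth, n_fragments // 5, seed=s[3])
    ctrl = normalize.binned_coverage(igg, primary, 100)
    called = domains.call_domains(track, control=ctrl)
    inter, truth_bp, called_bp = _bp_jaccard(truth.domains, called)
    return {
        "n_called": len(called),
        "recovered_frac": inter / truth_bp,
        "false_frac": (called_bp - inter) / truth_bp,
        "jaccard": inter / (truth_bp + called_bp - inter),
        "n": n_fragments,
    }


def differential_recovery(seed: int, n_fragments: int = 250_000,
                          n_per_class: int = 200,
                          workdir: str | None = None) -> dict:
    """Full pipeline on a 2-condition, 2-replicate + IgG design with
    planted shared / A-only / B-only domain classes; scores the knee-
    selected clustering against the planted classes by adjusted Rand
    index over the differential domains that map to a planted domain."""
    s = _seeds(seed, 8)
    primary = fragio.ChromSizes({"chr1": 50_000_000,
                                 "chr2": 50_000_000}, "primary")
    spike = fragio.ChromSizes({"spike1": 5_000_000}, "spike")
    truth_a, truth_b, all_domains, classes = synth.differential_truth(
        primary, spike, seed=s[0], n_shared=n_per_class,
        n_a_only=n_per_class, n_b_only=n_per_class)
    igg_truth = synth.make_truth("flat_background", primary, spike, seed=s[1])

    def _run(workdir: Path) -> dict:
        for chroms, name in ((primary, "primary"), (spike, "spike")):
            with open(workdir / f"{name}.sizes", "w") as fh:
                for c, n in chroms.sizes.items():
                    fh.write(f"{c}\t{n}\n")
        manifest = []
        sims = [("A_rep1", truth_a, n_fragments, s[2], "A"),
                ("A_rep2", truth_a, n_fragments, s[3], "A"),
                ("B_rep1", truth_b, n_fragments, s[4], "B"),
                ("B_rep2", truth_b, n_fragments, s[5], "B"),
                ("IgG", igg_truth, n_fragments // 2, s[6], "IgG")]
        for sid, truth, n, sd, group in sims:
            frags = synth.simulate_sample(truth, n, seed=sd, sample_id=sid)
            bed = workdir / f"{sid}.bed"
            fragio.write_fragment_bed(frags, bed)
            manifest.append(pipeline.SampleSpec(sample_id=sid, target="",
                                                fragments=bed, group=group))
        cfg = pipeline.PipelineConfig(
            primary_sizes=workdir / "primary.sizes",
            spike_sizes=workdir / "spike.sizes", samples=manifest,
            outdir=workdir / "out", call_bin_width=100,
            threshold_quantile=0.001, control_group="IgG",
            restarts=10, seed=s[7])
        report = pipeline.run_pipeline(cfg)
        import pandas as pd
        clusters = pd.read_csv(workdir / "out" / "clusters.tsv", sep="\t")
        regions = fragio.RegionSet("diff",
                                   df=clusters[["chrom", "start", "end"]])
        # map each differential domain to the planted class it overlaps most
        truth_class, cluster_label = [], []
        td = all_domains.df
        for row, cl in zip(regions.df.itertuples(index=False),
                           clusters["cluster"]):
            sub = td[(td["chrom"] == row.chrom) & (td["start"] < row.end)
                     & (td["end"] > row.start)]
            if len(sub) == 0:
                continue
            ov = np.minimum(sub["end"], row.end) - np.maximum(sub["start"],
                                                              row.start)
            truth_class.append(classes[sub.index[int(np.argmax(ov))]])
            cluster_label.append(cl)
        ari = adjusted_rand_score(truth_class, cluster_label)
        return {"selected_k": report["stages"]["selected_k"],
                "ari": float(ari),
                "n_differential_domains": report["stages"]["differential_domains"],
                "n_scored": len(truth_class),
                "n": n_fragments}

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return _run(Path(tmp))
    return _run(Path(workdir))


def contrast_recovery(seed: int, fold: float = 10.0,
                      n_fragments: int = 1_200_000) -> dict:
    """Two samples with identical domain occupancy but a planted ``fold``
    difference in per-domain signal and consequently unequal spike depths;
    recovers the fold as the ratio of FPK + spike-constant scaled medians."""
    s = _seeds(seed, 3)
    primary = fragio.ChromSizes({"chr1": 20_000_000,
                                 "chr2": 20_000_000}, "primary")
    spike = fragio.ChromSizes({"spike1": 2_000_000}, "spike")
    truth_hi = synth.make_truth("domain_mark", primary, spike, seed=s[0],
                                n_domains=60, domain_min_len=10_000,
                                domain_max_len=50_000, domain_multiplier=20.0)
    truth_lo = truth_hi.with_multipliers_scaled(1.0 / fold)
    frags_hi = synth.simulate_sample(truth_hi, n_fragments, seed=s[1],
                                     sample_id="hi")
    frags_lo = synth.simulate_sample(truth_lo, n_fragments, seed=s[2],
                                     sample_id="lo")
    raw = cq.signal_matrix(truth_hi.domains,
                           [(frags_hi, None), (frags_lo, None)],
                           spike_scale=False)
    constants = {"hi": normalize.spike_scale_factor(frags_hi.spike_count).factor,
                 "lo": normalize.spike_scale_factor(frags_lo.spike_count).factor}
    fpk = cq.fpk_scale(raw, constants=constants)
    med_hi, med_lo = np.median(fpk.values, axis=0)
    return {"fold_recovered": float(med_hi / med_lo),
            "spike_reads_hi": frags_hi.spike_count,
            "spike_reads_lo": frags_lo.spike_count,
            "n": n_fragments}


def titration_linearity(seed: int,
                        depths: tuple[int, ...] = (100_000, 200_000,
                                                   400_000, 800_000)) -> dict:
    """Depth titration at the fixed 1:20 spike ratio: raw window counts
    track spike reads linearly; spike-scaled signal stays constant."""
    s = _seeds(seed, 1 + len(depths))
    primary, spike = synth.toy_genome()
    truth = synth.make_truth("domain_mark", primary, spike, seed=s[0])
    raw, spikes, scaled = [], [], []
    for sd, n in zip(s[1:], depths):
        frags = synth.simulate_sample(truth, n, seed=sd)
        scale = normalize.spike_scale_factor(frags.spike_count)
        total = float(normalize.binned_coverage(frags, primary, 5000).total())
        raw.append(total)
        spikes.append(frags.spike_count)
        scaled.append(total * scale.factor)
    r2 = float(np.corrcoef(spikes, raw)[0, 1] ** 2)
    scaled = np.array(scaled)
    return {"r2": r2,
            "scaled_signal_rel_range": float(np.ptp(scaled) / scaled.mean()),
            "n": min(depths)}


def deposition_regime_contrast(seed: int, n_fragments: int = 1_000_000,
                               n_tss: int = 200) -> dict:
    """Promoter-turnover vs replication-coupled deposition signatures:
    ranked 5 kb bin-curve head/tail ratios and TSS top/bottom-decile
    signal ratios for the two regimes at equal depth."""
    s = _seeds(seed, 4)
    primary, spike = synth.toy_genome()
    rng = np.random.default_rng(s[0])
    tss = synth.sample_tss(rng, primary, n_tss, margin=2000)
    active = [tss[i] for i in rng.choice(n_tss, size=n_tss // 2,
                                         replace=False)]
    peaky = synth.make_truth("turnover_peaky", primary, spike, seed=s[1],
                             n_peaks=len(active), tss=sorted(active))
    flat = synth.make_truth("replication_coupled_uniform", primary, spike,
                            seed=s[1])
    out = {}
    for name, truth, sd in (("peaky", peaky, s[2]), ("uniform", flat, s[3])):
        frags = synth.simulate_sample(truth, n_fragments, seed=sd)
        scale = normalize.spike_scale_factor(frags.spike_count)
        track = normalize.binned_coverage(frags, primary, 5000)
        out[f"{name}_head_tail"] = normalize.head_tail_ratio(
            normalize.ranked_bin_counts(track))
        profile = cq.tss_matrix(frags, scale, tss, window=1000)
        out[f"{name}_decile_ratio"] = cq.decile_contrast(profile)
    out["n"] = n_fragments
    return out


def knee_recovery_rate(seed: int, n_runs: int = 100,
                       restarts: int = 10) -> dict:
    """Fraction of seeded runs in which the knee rule recovers 4 planted,
    well-separated row clusters."""
    s = _seeds(seed, n_runs)
    hits = 0
    for sd in s:
        matrix, _ = synth.planted_matrix(seed=sd)
        a = cq.select_k_knee(matrix, seed=sd, restarts=restarts)
        hits += a.selected_k == 4
    return {"rate": hits / n_runs, "hits": hits, "n": n_runs}
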