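"""Synthetic multi-sample CUT&RUN fragment data with planted ground truth.

Four deposition regimes are emulated, matching the biology of histone
variants and controls:

* ``domain_mark`` — broad silenced domains (tens to hundreds of kb) of
  elevated signal over a low background: an H3K27me3-like Polycomb
  profile.
* ``turnover_peaky`` — narrow promoter-localized peaks over a low uniform
  background: an H3.3-type profile deposited at sites of active histone
  turnover (replication-independent assembly).
* ``replication_coupled_uniform`` — genome-wide uniform signal with no
  planted features: an H3.1-type profile deposited everywhere behind
  replication forks.
* ``flat_background`` — uniform low-rate noise: an IgG / wild-type-like
  control.

Every sample additionally carries spike-in fragments drawn uniformly over
a separate spike genome, at an intensity share derived from the spike
cell ratio (default 1:20, the standard calibration mix) and the relative
genome masses. Fragment counts, not read counts, are the unit everywhere.

Fragment start positions are drawn from the piecewise-constant intensity
implied by the truth model (background x multipliers); fragment lengths
are nucleosomal, truncated-normal (default 170 +- 25 bp, minimum 50 bp).
All draws are seeded and byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragio import ChromSizes, FragmentSet, RegionSet, regions_from_intervals

PROFILES = ("domain_mark", "turnover_peaky",
            "replication_coupled_uniform", "flat_background")

DEFAULT_SPIKE_RATIO = 1.0 / 20.0  # spike cells per primary cell


def toy_genome(primary_chrom_bp: int = 5_000_000, n_primary: int = 2,
               spike_chrom_bp: int = 500_000) -> tuple[ChromSizes, ChromSizes]:
    """Default toy genome: 2 primary chromosomes of 5 Mb + one 500 kb spike
    chromosome — big enough for 5 kb bins and 10 kb/3 kb length filters to
    be meaningful, small enough for seconds-scale tests."""
    primary = ChromSizes({f"chr{i + 1}": primary_chrom_bp
                          for i in range(n_primary)}, label="primary")
    spike = ChromSizes({"spike1": spike_chrom_bp}, label="spike")
    return primary, spike


@dataclass
class TruthModel:
    """Planted ground truth for one deposition regime."""

    profile: str
    genome: ChromSizes
    spike_genome: ChromSizes
    domains: RegionSet
    domain_multipliers: np.ndarray  # one per planted domain, >= 1
    peaks: list[tuple[str, int, int, float]]  # (chrom, tss, width, multiplier)
    background_rate: float = 1.0  # relative fragments per kb of background
    spike_ratio: float = DEFAULT_SPIKE_RATIO
    frag_len_mean: float = 170.0
    frag_len_sd: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        self.domain_multipliers = np.asarray(self.domain_multipliers, float)
        if len(self.domain_multipliers) != len(self.domains):
            raise ValueError("one multiplier per planted domain required")
        if (self.domain_multipliers < 1).any():
            raise ValueError("domain multipliers must be >= 1")
        if any(m < 1 for *_, m in self.peaks):
            raise ValueError("peak multipliers must be >= 1")
        if self.background_rate <= 0:
            raise ValueError("background rate must be positive")
        if not 0 < self.spike_ratio < 1:
            raise ValueError("spike ratio must be in (0, 1)")

    # ----- intensity model -------------------------------------------------

    def intensity_segments(self) -> pd.DataFrame:
        """Piecewise-constant per-bp intensity over primary + spike genomes.

        Columns: chrom, start, end, rate (relative per-bp). Background is
        ``background_rate`` per kb; planted domains/peaks multiply it; the
        spike genome is uniform at background x spike_ratio per bp.
        """
        per_bp = self.background_rate / 1000.0
        rows: list[tuple[str, int, int, float]] = []
        features: dict[str, list[tuple[int, int, float]]] = {}
        for (c, s, e), m in zip(
                self.domains.df[["chrom", "start", "end"]].itertuples(index=False),
                self.domain_multipliers):
            features.setdefault(c, []).append((int(s), int(e), float(m)))
        for chrom, pos, width, mult in self.peaks:
            lo = max(0, pos - width // 2)
            hi = min(self.genome[chrom], pos + (width - width // 2))
            features.setdefault(chrom, []).append((lo, hi, float(mult)))
        for chrom in self.genome.chroms:
            length = self.genome[chrom]
            feats = sorted(features.get(chrom, []))
            cursor = 0
            for lo, hi, mult in feats:
                if lo < cursor:
                    raise ValueError(f"overlapping planted features on {chrom}")
                if lo > cursor:
                    rows.append((chrom, cursor, lo, per_bp))
                rows.append((chrom, lo, hi, per_bp * mult))
                cursor = hi
            if cursor < length:
                rows.append((chrom, cursor, length, per_bp))
        for chrom in self.spike_genome.chroms:
            rows.append((chrom, 0, self.spike_genome[chrom],
                         per_bp * self.spike_ratio))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])

    def spike_share(self) -> float:
        """Expected fraction of fragments originating from the spike genome."""
        seg = self.intensity_segments()
        mass = (seg["end"] - seg["start"]) * seg["rate"]
        is_spike = seg["chrom"].isin(self.spike_genome.sizes)
        return float(mass[is_spike].sum() / mass.sum())

    def domain_fragment_fraction(self) -> float:
        """Expected fraction of *primary* fragments inside planted domains."""
        seg = self.intensity_segments()
        primary = seg[seg["chrom"].isin(self.genome.sizes)]
        mass = ((primary["end"] - primary["start"]) * primary["rate"]).to_numpy()
        dom = np.zeros(len(primary), dtype=bool)
        for i, row in enumerate(primary.itertuples(index=False)):
            sub = self.domains.df[(self.domains.df["chrom"] == row.chrom)
                                  & (self.domains.df["start"] <= row.start)
                                  & (self.domains.df["end"] >= row.end)]
            dom[i] = len(sub) > 0
        total = mass.sum()
        return float(mass[dom].sum() / total) if total else 0.0

    def with_multipliers_scaled(self, factor: float) -> "TruthModel":
        """Same occupancy, planted per-domain signal scaled by ``factor``
        (used to plant quantitative contrasts between samples)."""
        mult = np.maximum(self.domain_multipliers * factor, 1.0)
        peaks = [(c, p, w, max(m * factor, 1.0)) for c, p, w, m in self.peaks]
        return TruthModel(profile=self.profile, genome=self.genome,
                          spike_genome=self.spike_genome, domains=self.domains,
                          domain_multipliers=mult, peaks=peaks,
                          background_rate=self.background_rate,
                          spike_ratio=self.spike_ratio,
                          frag_len_mean=self.frag_len_mean,
                          frag_len_sd=self.frag_len_sd, seed=self.seed)


def _sample_domains(rng: np.random.Generator, genome: ChromSizes,
                    n_domains: int, min_len: int, max_len: int,
                    gap: int) -> list[tuple[str, int, int]]:
    """Place non-overlapping broad domains, spread across chromosomes."""
    chroms = genome.chroms
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(n_domains, weights)
    out = []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        length = genome[chrom]
        lens = rng.integers(min_len, max_len + 1, size=n)
        free = length - int(lens.sum()) - gap * (n + 1)
        if free < 0:
            raise ValueError("genome too small for requested domains")
        gaps = rng.multinomial(free, np.ones(n + 1) / (n + 1))
        cursor = 0
        for i in range(n):
            cursor += gap + int(gaps[i])
            out.append((chrom, cursor, cursor + int(lens[i])))
            cursor += int(lens[i])
    return out


def make_truth(profile: str, genome: ChromSizes, spike_genome: ChromSizes,
               seed: int, n_domains: int = 10, domain_multiplier: float = 20.0,
               domain_min_len: int = 10_000, domain_max_len: int = 200_000,
               n_peaks: int = 100, peak_width: int = 1000,
               peak_multiplier: float = 50.0, background_rate: float = 1.0,
               peaky_background_rate: float = 1.0,
               spike_ratio: float = DEFAULT_SPIKE_RATIO,
               tss: list[tuple[str, int]] | None = None) -> TruthModel:
    """Build a seeded planted-truth model for one deposition regime.

    ``domain_mark`` plants ``n_domains`` broad domains of 10-200 kb (by
    default) at ``domain_multiplier`` x background; ``turnover_peaky``
    plants ``n_peaks`` promoter peaks (at given TSSs, or sampled ones) at
    ``peak_multiplier`` x background; the uniform profiles plant nothing.
    """
    rng = np.random.default_rng(seed)
    domains: list[tuple[str, int, int]] = []
    multipliers: list[float] = []
    peaks: list[tuple[str, int, int, float]] = []
    if profile == "domain_mark":
        domains = _sample_domains(rng, genome, n_domains,
                                  domain_min_len, domain_max_len, gap=5000)
        multipliers = [domain_multiplier] * len(domains)
    elif profile == "turnover_peaky":
        if tss is None:
            tss = sample_tss(rng, genome, n_peaks, margin=peak_width)
        peaks = [(c, p, peak_width, peak_multiplier) for c, p in tss[:n_peaks]]
        peaks.sort()
        background_rate = peaky_background_rate
    elif profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    return TruthModel(profile=profile, genome=genome,
                      spike_genome=spike_genome,
                      domains=regions_from_intervals("planted_domains", domains),
                      domain_multipliers=np.array(multipliers),
                      peaks=peaks, background_rate=background_rate,
                      spike_ratio=spike_ratio, seed=seed)


def sample_tss(rng: np.random.Generator, genome: ChromSizes, n: int,
               margin: int = 2000, min_spacing: int = 8000
               ) -> list[tuple[str, int]]:
    """Sample well-spaced TSS positions across a genome (for planting
    promoter peaks and for TSS-anchored summaries)."""
    chroms = genome.chroms
    weights = np.array([genome[c] for c in chroms], float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(n, weights)
    out = []
    for chrom, cnt in zip(chroms, per_chrom):
        hi = genome[chrom] - margin
        grid = np.arange(margin, hi, min_spacing)
        if cnt > len(grid):
            raise ValueError("genome too small for requested TSS count")
        picks = rng.choice(len(grid), size=cnt, replace=False)
        jitter = rng.integers(0, min_spacing // 4, size=cnt)
        out.extend((chrom, int(grid[i] + j)) for i, j in zip(picks, jitter))
    return sorted(out)


def simulate_sample(truth: TruthModel, n_fragments: int, seed: int,
                    sample_id: str = "sample", target: str = "") -> FragmentSet:
    """Draw a seeded FragmentSet of ``n_fragments`` from the truth intensity.

    Segment counts are multinomial in the segment intensity masses; start
    positions are uniform within the segment; lengths are truncated normal
    (>= 50 bp), ends clipped at the chromosome edge.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    seg = truth.intensity_segments()
    mass = ((seg["end"] - seg["start"]) * seg["rate"]).to_numpy()
    p = mass / mass.sum()
    counts = rng.multinomial(n_fragments, p)
    chroms, starts = [], []
    for (row, cnt) in zip(seg.itertuples(index=False), counts):
        if cnt == 0:
            continue
        pos = rng.integers(row.start, row.end, size=cnt)
        chroms.append(np.full(cnt, row.chrom, dtype=object))
        starts.append(pos)
    chrom_arr = np.concatenate(chroms)
    start_arr = np.concatenate(starts).astype(np.int64)
    lengths = rng.normal(truth.frag_len_mean, truth.frag_len_sd,
                         size=len(start_arr))
    lengths = np.maximum(np.rint(lengths), 50).astype(np.int64)
    end_arr = start_arr + lengths
    all_sizes = {**truth.genome.sizes, **truth.spike_genome.sizes}
    limits = np.array([all_sizes[c] for c in chrom_arr], dtype=np.int64)
    end_arr = np.minimum(end_arr, limits)
    df = pd.DataFrame({"chrom": chrom_arr.astype(str), "start": start_arr,
                       "end": end_arr})
    is_spike = df["chrom"].isin(truth.spike_genome.sizes)
    frags = FragmentSet(
        sample_id=sample_id, target=target or truth.profile,
        primary=df[~is_spike].sort_values(["chrom", "start", "end"],
                                          kind="mergesort").reset_index(drop=True),
        spike=df[is_spike].sort_values(["chrom", "start", "end"],
                                       kind="mergesort").reset_index(drop=True))
    return frags


def differential_truth(genome: ChromSizes, spike_genome: ChromSizes,
                       seed: int, n_shared: int = 200, n_a_only: int = 200,
                       n_b_only: int = 200, domain_min_len: int = 10_000,
                       domain_max_len: int = 25_000,
                       domain_multiplier: float = 20.0,
                       background_rate: float = 1.0,
                       spike_ratio: float = DEFAULT_SPIKE_RATIO
                       ) -> tuple[TruthModel, TruthModel, RegionSet, list[str]]:
    """Plant a two-condition domain design with shared / A-only / B-only
    domain classes (the structure behind differential-domain clustering).

    Returns the condition-A truth, condition-B truth, the combined planted
    domain set, and a per-domain class label list aligned with it.
    """
    rng = np.random.default_rng(seed)
    n_total = n_shared + n_a_only + n_b_only
    placed = _sample_domains(rng, genome, n_total, domain_min_len,
                             domain_max_len, gap=5000)
    classes = np.array(["shared"] * n_shared + ["A"] * n_a_only
                       + ["B"] * n_b_only)
    rng.shuffle(classes)
    all_domains = regions_from_intervals("planted_all", placed)
    ordered = list(all_domains.df[["chrom", "start", "end"]]
                   .itertuples(index=False, name=None))
    # map classes onto the sorted order via the placement order
    order_idx = {iv: i for i, iv in enumerate(sorted(placed))}
    classes_sorted = [classes[order_idx[iv]] for iv in ordered]

    def _truth(keep: set[str]) -> TruthModel:
        doms = [iv for iv, c in zip(ordered, classes_sorted) if c in keep]
        return TruthModel(
            profile="domain_mark", genome=genome, spike_genome=spike_genome,
            domains=regions_from_intervals("planted_domains", doms),
            domain_multipliers=np.full(len(doms), domain_multiplier),
            peaks=[], background_rate=background_rate,
            spike_ratio=spike_ratio, seed=seed)

    return (_truth({"shared", "A"}), _truth({"shared", "B"}),
            all_domains, classes_sorted)


DEFAULT_CLUSTER_PATTERNS = np.array([
    [9.0, 1.0, 1.0],   # present only in the first line
    [9.0, 8.0, 4.0],   # shared everywhere (low absolute in the third)
    [1.0, 8.0, 4.0],   # absent in the first, present in the others
    [4.0, 1.0, 7.0],   # present mainly in the third
])


def planted_matrix(n_per_cluster: int = 150,
                   patterns: np.ndarray | None = None,
                   noise_sd: float = 0.7, seed: int = 0,
                   sample_names: list[str] | None = None):
    """A region x sample count matrix with planted row clusters.

    Rows are drawn per cluster as log2-normal counts around the cluster's
    pattern (log2 scale): count = max(2**N(pattern, noise_sd) - 1, 0).
    Default patterns mimic presence/absence contrasts between three cell
    lines. Returns (SignalMatrix, true_labels).
    """
    from .clusterquant import SignalMatrix

    if patterns is None:
        patterns = DEFAULT_CLUSTER_PATTERNS
    patterns = np.asarray(patterns, dtype=float)
    rng = np.random.default_rng(seed)
    n_clusters, n_samples = patterns.shape
    rows, labels = [], []
    for c in range(n_clusters):
        rows.append(rng.normal(patterns[c], noise_sd,
                               size=(n_per_cluster, n_samples)))
        labels.extend([c] * n_per_cluster)
    counts = np.maximum(2.0 ** np.vstack(rows) - 1.0, 0.0)
    n = len(counts)
    regions = regions_from_intervals(
        "planted_rows", [("chrM", i * 2000, i * 2000 + 1000) for i in range(n)])
    names = sample_names or [f"sample{j + 1}" for j in range(n_samples)]
    matrix = SignalMatrix(regions=regions, samples=names, values=counts)
    return matrix, np.array(labels)


# ----- truth serialization --------------------------------------------------

def truth_to_json(truth: TruthModel) -> str:
    payload = {
        "profile": truth.profile,
        "genome": {"sizes": truth.genome.sizes, "label": truth.genome.label},
        "spike_genome": {"sizes": truth.spike_genome.sizes,
                         "label": truth.spike_genome.label},
        "domains": truth.domains.df[["chrom", "start", "end"]]
                        .to_dict(orient="records"),
        "domain_multipliers": truth.domain_multipliers.tolist(),
        "peaks": [list(p) for p in truth.peaks],
        "background_rate": truth.background_rate,
        "spike_ratio": truth.spike_ratio,
        "frag_len_mean": truth.frag_len_mean,
        "frag_len_sd": truth.frag_len_sd,
        "seed": truth.seed,
    }
    return json.dumps(payload, indent=2)


def truth_from_json(text: str) -> TruthModel:
    d = json.loads(text)
    domains = regions_from_intervals(
        "planted_domains",
        [(r["chrom"], r["start"], r["end"]) for r in d["domains"]])
    return TruthModel(
        profile=d["profile"],
        genome=ChromSizes(d["genome"]["sizes"], label=d["genome"]["label"]),
        spike_genome=ChromSizes(d["spike_genome"]["sizes"],
                                label=d["spike_genome"]["label"]),
        domains=domains,
        domain_multipliers=np.array(d["domain_multipliers"]),
        peaks=[tuple(p) for p in d["peaks"]],
        background_rate=d["background_rate"], spike_ratio=d["spike_ratio"],
        frag_len_mean=d["frag_len_mean"], frag_len_sd=d["frag_len_sd"],
        seed=d["seed"])


def truth_report(truth: TruthModel, domains_bed, peaks_bed, params_json) -> None:
    """Serialize planted domains (BED3), peaks (BED3 around each TSS) and
    the full parameter JSON for test harnesses."""
    from .fragio import write_region_bed
    write_region_bed(truth.domains, domains_bed)
    with open(peaks_bed, "w") as fh:
        for chrom, pos, width, _ in truth.peaks:
            lo = max(0, pos - width // 2)
            fh.write(f"{chrom}\t{lo}\t{lo + width}\n")
    with open(params_json, "w") as fh:
        fh.write(truth_to_json(truth))
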