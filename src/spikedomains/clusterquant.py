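"""Region x sample signal matrices, clustering, and quantification.

Pipeline tail: count each sample's fragments over a fixed region universe
(>=1 bp overlap), spike-scale the counts, cluster regions by k-means with
the number of clusters chosen at the knee of the within-cluster-distance
curve, and summarize per-cluster signal after fragments-per-kilobase (FPK)
and spike-constant scaling. Also provides the overlap/ordering/correlation
summaries used to compare domain repertoires between cell lines: fraction
of one domain set found in another, TSS-anchored signal heatmap matrices
ordered by promoter signal, and squared Pearson correlation of promoter
signal with expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .fragio import FragmentSet, RegionSet
from .normalize import SpikeScale


@dataclass
class SignalMatrix:
    """regions x samples fragment counts, with per-sample scaling records."""

    regions: RegionSet
    samples: list[str]
    values: np.ndarray  # shape (n_regions, n_samples), float
    spike_applied: dict[str, bool] = field(default_factory=dict)
    fpk_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("matrix shape does not match regions x samples")
        if (self.values < 0).any():
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{c}:{s}-{e}" for c, s, e in
               self.regions.df[["chrom", "start", "end"]].itertuples(index=False)]
        return pd.DataFrame(self.values, index=idx, columns=self.samples)


@dataclass
class ClusterAssignment:
    """k-means result plus the within-cluster-distance scan used to pick k."""

    k: int
    labels: np.ndarray  # cluster ids 1..k per region
    withinss_by_k: dict[int, float]
    selected_k: int | None
    seed: int
    restarts: int


@dataclass(frozen=True)
class OverlapSummary:
    """shared / total interval counts with the percent they imply."""

    shared: int
    total: int
    decimals: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.shared <= self.total:
            raise ValueError("need 0 <= shared <= total")

    @property
    def percent(self) -> float:
        """100 x shared/total, round-half-up at ``decimals`` places."""
        return round_half_up(100.0 * self.shared / self.total, self.decimals)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal-style round-half-up (0.5 always rounds away from zero)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _overlap_counts(regions: RegionSet, frag_df: pd.DataFrame) -> np.ndarray:
    """Fragments overlapping each region by >=1 bp (regions non-overlapping).

    Per chromosome, with fragment starts and ends each sorted:
    count(r) = #{start < r.end} - #{end <= r.start}.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    reg = regions.df.reset_index(drop=True)
    for chrom, sub in reg.groupby("chrom", sort=False):
        fr = frag_df[frag_df["chrom"] == chrom]
        if len(fr) == 0:
            continue
        starts = np.sort(fr["start"].to_numpy())
        ends = np.sort(fr["end"].to_numpy())
        a = np.searchsorted(starts, sub["end"].to_numpy(), side="left")
        b = np.searchsorted(ends, sub["start"].to_numpy(), side="right")
        counts[sub.index.to_numpy()] = a - b
    return counts


def signal_matrix(regions: RegionSet,
                  samples: list[tuple[FragmentSet, SpikeScale | None]],
                  spike_scale: bool = True) -> SignalMatrix:
    """Count primary fragments per region per sample, optionally spike-scaled.

    Region sets are non-overlapping by construction, so each fragment is
    counted unambiguously per region.
    """
    names, cols, applied = [], [], {}
    for frags, scale in samples:
        counts = _overlap_counts(regions, frags.primary).astype(float)
        if spike_scale:
            if scale is None:
                raise ValueError(f"sample {frags.sample_id}: spike scale required")
            counts = counts * scale.factor
        names.append(frags.sample_id)
        applied[frags.sample_id] = bool(spike_scale)
        cols.append(counts)
    values = np.column_stack(cols) if cols else np.zeros((len(regions), 0))
    return SignalMatrix(regions=regions, samples=names, values=values,
                        spike_applied=applied)


def fpk_scale(matrix: SignalMatrix,
              constants: dict[str, float] | None = None) -> SignalMatrix:
    """Scale counts to fragments per kilobase, then by per-sample constants.

    FPK = count x 1000 / region length; the per-sample constant is the
    spike calibration constant (inversely proportional to spike reads).
    If the matrix was already spike-scaled at construction, pass no
    constants (they default to 1) to avoid double calibration.
    """
    if matrix.fpk_applied:
        raise ValueError("matrix already FPK-scaled")
    lengths = matrix.regions.lengths().astype(float)
    values = matrix.values * (1000.0 / lengths)[:, None]
    if constants is not None:
        factors = np.array([constants[s] for s in matrix.samples])
        values = values * factors[None, :]
    out = SignalMatrix(regions=matrix.regions, samples=list(matrix.samples),
                       values=values, spike_applied=dict(matrix.spike_applied))
    out.fpk_applied = True
    return out


def _feature_matrix(matrix: SignalMatrix, log_transform: bool) -> np.ndarray:
    return np.log2(matrix.values + 1.0) if log_transform else matrix.values


def kmeans_cluster(matrix: SignalMatrix, k: int, seed: int,
                   restarts: int = 25, log_transform: bool = True,
                   withinss_by_k: dict[int, float] | None = None,
                   selected_k: int | None = None) -> ClusterAssignment:
    """Lloyd k-means on matrix rows (Euclidean), best of ``restarts``
    initializations by within-cluster sum of squares; deterministic for a
    given seed. Rows are log2(x+1)-transformed by default."""
    n = len(matrix.regions)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot fit {k} clusters to {n} rows")
    X = _feature_matrix(matrix, log_transform)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(X) + 1
    wss = dict(withinss_by_k or {})
    wss[k] = float(km.inertia_)
    return ClusterAssignment(k=k, labels=labels, withinss_by_k=wss,
                             selected_k=selected_k, seed=seed,
                             restarts=restarts)


def _total_ss(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


def knee_from_curve(ks: list[int], withinss: list[float]) -> int:
    """k maximizing the discrete second difference W(k-1) - 2W(k) + W(k+1)
    (largest curvature of the elbow plot); ties go to the smaller k.

    The curve must include one point on each side of every candidate, so
    candidates are ks[1:-1].
    """
    if len(ks) < 3:
        raise ValueError("need at least 3 curve points to locate a knee")
    w = np.asarray(withinss, dtype=float)
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]
    return int(ks[1 + int(np.argmax(curvature))])


def select_k_knee(matrix: SignalMatrix, k_min: int = 2, k_max: int = 15,
                  seed: int = 0, restarts: int = 25,
                  log_transform: bool = True) -> ClusterAssignment:
    """Scan k in [k_min, k_max], pick the knee of the within-cluster-distance
    curve, and return the assignment at the selected k.

    The curve is anchored at k_min - 1 (for k_min = 2 that is the total sum
    of squares, no clustering needed) so the first scanned k is itself a
    knee candidate; candidates are k_min .. k_max - 1.
    """
    if k_min < 2 or k_max <= k_min:
        raise ValueError("need 2 <= k_min < k_max")
    if len(matrix.regions) < k_max:
        raise ValueError("fewer rows than k_max")
    X = _feature_matrix(matrix, log_transform)
    wss: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    if k_min == 2:
        wss[1] = _total_ss(X)
    else:
        a = kmeans_cluster(matrix, k_min - 1, seed, restarts, log_transform)
        wss[k_min - 1] = a.withinss_by_k[k_min - 1]
    for k in range(k_min, k_max + 1):
        a = kmeans_cluster(matrix, k, seed, restarts, log_transform)
        wss[k] = a.withinss_by_k[k]
        assignments[k] = a.labels
    ks = sorted(wss)
    curve = [wss[k] for k in ks]
    if any(curve[i] < curve[i + 1] for i in range(len(curve) - 1)):
        import logging
        logging.getLogger(__name__).warning(
            "within-cluster distance curve is not monotone (sampling noise); "
            "selecting max-curvature k regardless")
    best = knee_from_curve(ks, curve)
    return ClusterAssignment(k=best, labels=assignments[best],
                             withinss_by_k=wss, selected_k=best,
                             seed=seed, restarts=restarts)


def overlap_fraction(query: RegionSet, reference: RegionSet,
                     decimals: int = 1) -> OverlapSummary:
    """How many query intervals overlap >=1 reference interval by >=1 bp."""
    if len(query) == 0:
        raise ValueError("empty query region set: percent undefined")
    shared = 0
    for chrom, sub in query.df.groupby("chrom", sort=False):
        ref = reference.df[reference.df["chrom"] == chrom]
        if len(ref) == 0:
            continue
        rs = ref["start"].to_numpy()
        re_ = ref["end"].to_numpy()
        # reference sorted + disjoint: query q overlaps some reference iff
        # the last reference starting before q.end extends past q.start
        idx = np.searchsorted(rs, sub["end"].to_numpy(), side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = re_[idx[ok]] > sub["start"].to_numpy()[ok]
        shared += int(hit.sum())
    return OverlapSummary(shared=shared, total=len(query), decimals=decimals)


def tss_matrix(frags: FragmentSet, scale: SpikeScale,
               tss: list[tuple[str, int]], window: int = 1000,
               bin_width: int = 50, order_window: int = 500,
               sizes=None) -> pd.DataFrame:
    """Per-TSS spike-scaled fragment-count profile in [pos-window, pos+window).

    Rows are ordered descending by scaled fragment count within
    ±``order_window`` bp of the TSS (promoter signal). TSSs whose window
    runs off a chromosome edge keep zero-padded flanks.
    """
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be positive")
    n_bins = (2 * window) // bin_width
    profiles = np.zeros((len(tss), n_bins))
    order_scores = np.zeros(len(tss))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in frags.primary.groupby("chrom", sort=False):
        by_chrom[chrom] = (np.sort(sub["start"].to_numpy()),
                           np.sort(sub["end"].to_numpy()))
    for i, (chrom, pos) in enumerate(tss):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        lo = pos - window
        edges = lo + np.arange(n_bins + 1) * bin_width
        # fragments overlapping [edges[b], edges[b+1]) by >=1 bp:
        # #(start < hi) - #(end <= lo)
        n_start = np.searchsorted(starts, edges[1:], side="left")
        n_end = np.searchsorted(ends, edges[:-1], side="right")
        profiles[i] = n_start - n_end
        order_scores[i] = (np.searchsorted(starts, pos + order_window, "left")
                           - np.searchsorted(ends, pos - order_window, "right"))
    profiles *= scale.factor
    order_scores *= scale.factor
    order = np.argsort(-order_scores, kind="mergesort")
    idx = [f"{c}:{p}" for c, p in tss]
    df = pd.DataFrame(profiles[order],
                      index=[idx[i] for i in order],
                      columns=[(-window + b * bin_width) for b in range(n_bins)])
    df.attrs["order_scores"] = order_scores[order]
    return df


def decile_contrast(ordered_tss: pd.DataFrame) -> float:
    """Mean promoter signal in the top decile of TSS rows over the bottom
    decile — >~5x for turnover-deposited (promoter-peaked) profiles, ~1x
    for replication-coupled (uniform) profiles."""
    n = len(ordered_tss)
    n_dec = max(1, n // 10)
    top = float(ordered_tss.iloc[:n_dec].to_numpy().mean())
    bottom = float(ordered_tss.iloc[-n_dec:].to_numpy().mean())
    if bottom == 0:
        return np.inf if top > 0 else 1.0
    return top / bottom


def tss_window_correlation(frag_counts: np.ndarray,
                           expression: np.ndarray) -> float:
    """Squared Pearson correlation of log2(x+1) promoter fragment counts
    with log2(x+1) expression counts."""
    x = np.log2(np.asarray(frag_counts, dtype=float) + 1.0)
    y = np.log2(np.asarray(expression, dtype=float) + 1.0)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r ** 2)


def cluster_region_stats(matrix: SignalMatrix,
                         assignment: ClusterAssignment) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max; linear-interpolation
    quartiles) per (cluster, sample) of an FPK-scaled matrix."""
    rows = []
    for cluster in range(1, assignment.k + 1):
        mask = assignment.labels == cluster
        for j, sample in enumerate(matrix.samples):
            vals = matrix.values[mask, j]
            if len(vals) == 0:
                q = [np.nan] * 5
            else:
                q = np.percentile(vals, [0, 25, 50, 75, 100]).tolist()
            rows.append((cluster, sample, int(mask.sum()), *q))
    return pd.DataFrame(rows, columns=["cluster", "sample", "n", "min",
                                       "q1", "median", "q3", "max"])
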