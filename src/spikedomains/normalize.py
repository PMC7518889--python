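"""Spike-in calibration and binned coverage tracks.

The calibration model: every reaction receives a fixed quantity of
foreign-genome ("spike-in") chromatin, so the number of spike fragments
recovered measures recovery efficiency x sequencing depth. Dividing a
constant (default 10,000) by the spike read count gives a per-sample
scale factor; multiplying primary-genome signal by that factor puts all
samples on a common absolute scale.

Coverage is binned by summing base pairs of fragment overlap per bin
(pro-rata at bin boundaries), the convention used for genome-wide
signal-distribution plots at 5 kb resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragio import ChromSizes, FragmentSet

DEFAULT_SPIKE_CONSTANT = 10_000.0


class CalibrationError(ValueError):
    """Sample cannot be spike-normalized (e.g. zero spike reads)."""


@dataclass(frozen=True)
class SpikeScale:
    """Per-sample spike-in scale factor: constant / spike read count."""

    spike_reads: int
    constant: float = DEFAULT_SPIKE_CONSTANT

    def __post_init__(self) -> None:
        if self.spike_reads <= 0:
            raise CalibrationError(
                "spike read count must be positive to calibrate a sample")
        if self.constant <= 0:
            raise CalibrationError("spike constant must be positive")

    @property
    def factor(self) -> float:
        return self.constant / self.spike_reads


def spike_scale_factor(spike_reads: int,
                       constant: float = DEFAULT_SPIKE_CONSTANT) -> SpikeScale:
    """Build the spike calibration for a sample from its spike read count."""
    return SpikeScale(spike_reads=int(spike_reads), constant=float(constant))


@dataclass
class CoverageTrack:
    """Per-bin signal over a genome; ``ceil(length / bin_width)`` bins per chromosome.

    ``values`` maps chromosome -> float array of per-bin base-pair counts
    (or scaled signal once a spike factor has been applied).
    """

    sizes: ChromSizes
    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    scale_applied: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom in self.sizes.chroms:
            n = self.n_bins(chrom)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(f"bin count mismatch on {chrom}")

    def n_bins(self, chrom: str) -> int:
        return -(-self.sizes[chrom] // self.bin_width)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def bin_frame(self) -> pd.DataFrame:
        """All bins as (chrom, start, end, value), ends clipped to chromosome."""
        frames = []
        for chrom in self.sizes.chroms:
            vals = self.values[chrom]
            starts = np.arange(len(vals), dtype=np.int64) * self.bin_width
            ends = np.minimum(starts + self.bin_width, self.sizes[chrom])
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                        "end": ends, "value": vals}))
        return pd.concat(frames, ignore_index=True)


def binned_coverage(frags: FragmentSet, sizes: ChromSizes,
                    bin_width: int = 5000) -> CoverageTrack:
    """Sum base pairs of primary-fragment overlap in fixed-width bins.

    A fragment spanning a bin boundary contributes to each bin pro-rata
    by overlap, so the track total equals total fragment base pairs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    track = CoverageTrack(sizes=sizes, bin_width=bin_width)
    for chrom, sub in frags.primary.groupby("chrom", sort=False):
        if chrom not in sizes:
            raise ValueError(f"fragment chromosome {chrom!r} not in genome")
        bins = track.values[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        first = starts // bin_width
        last = (ends - 1) // bin_width
        # fragments are short relative to bins: iterate bin offsets, vectorize
        # over fragments
        max_span = int((last - first).max()) if len(starts) else 0
        for k in range(max_span + 1):
            b = first + k
            active = b <= last
            if not active.any():
                break
            bb = b[active]
            lo = np.maximum(starts[active], bb * bin_width)
            hi = np.minimum(ends[active], (bb + 1) * bin_width)
            np.add.at(bins, bb, (hi - lo).astype(float))
    return track


def scale_track(track: CoverageTrack, scale: SpikeScale) -> CoverageTrack:
    """Multiply every bin by the spike factor; refuses to scale twice."""
    if track.scale_applied is not None:
        raise CalibrationError("track already spike-scaled")
    scaled = {c: v * scale.factor for c, v in track.values.items()}
    return CoverageTrack(sizes=track.sizes, bin_width=track.bin_width,
                         values=scaled, scale_applied=scale.factor)


def ranked_bin_counts(track: CoverageTrack) -> pd.DataFrame:
    """Bin values sorted descending, bin identities retained.

    Ties are broken by genomic position (chromosome order in the sizes
    file, then start), so the ranking is deterministic.
    """
    df = track.bin_frame()
    df["rank"] = np.arange(len(df))
    df = df.sort_values(["value", "rank"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.drop(columns="rank")


def head_tail_ratio(ranked: pd.DataFrame, head_frac: float = 0.01,
                    tail_frac: float = 0.5) -> float:
    """Mean signal in the top ``head_frac`` of ranked bins over the mean in
    the bottom ``tail_frac`` — a one-number summary of how peaked a ranked
    bin-count curve is (steep head = localized deposition, flat curve =
    genome-wide deposition)."""
    n = len(ranked)
    n_head = max(1, int(round(n * head_frac)))
    n_tail = max(1, int(round(n * tail_frac)))
    head = float(ranked["value"].iloc[:n_head].mean())
    tail = float(ranked["value"].iloc[-n_tail:].mean())
    if tail == 0:
        return np.inf if head > 0 else 1.0
    return head / tail
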