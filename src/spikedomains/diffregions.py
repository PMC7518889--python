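"""Differential-domain definition by interval partitioning.

Merged domain lists from several samples are decomposed into the maximal
disjoint segments of constant set-membership ("partitioning": every start
or end coordinate of any input becomes a segment boundary). Segments that
share a boundary with another segment arise exactly where membership
changes between samples; in each such run of adjacent segments only the
"dominant" (long) segments are retained, via a length filter:

* adjacent segments shorter than ``adjacent_min`` (default 10 kb) are
  dropped, keeping only the dominant segment of each partitioning overlap
  and avoiding doubly counting adjacent pieces of one underlying domain;
* free-standing segments shorter than ``freestanding_min`` (default 3 kb)
  are dropped.

Thresholds are strict: a segment of exactly the threshold length is kept.
The surviving segments are the differential-domain universe fed to
clustering. Membership labels are carried through as annotation so
downstream summaries can report per-sample provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragio import RegionSet


@dataclass
class PartitionedSegments:
    """Disjoint exact cover of the union of several labeled region sets.

    ``df`` columns: chrom, start, end, membership (frozenset of input
    labels), adj_left / adj_right (True where the segment shares that
    boundary coordinate with another segment).
    """

    labels: tuple[str, ...]
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_bp(self) -> int:
        if len(self.df) == 0:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def is_adjacent(self) -> np.ndarray:
        return (self.df["adj_left"] | self.df["adj_right"]).to_numpy()

    def to_region_set(self, label: str = "segments") -> RegionSet:
        return RegionSet(label=label, df=self.df[["chrom", "start", "end"]])


def _member_mask(boundaries: np.ndarray, starts: np.ndarray,
                 ends: np.ndarray) -> np.ndarray:
    """For candidate segments [boundaries[i], boundaries[i+1]), True where
    the segment lies inside one of the sorted intervals (starts, ends).

    Candidate segments never cross an interval boundary of any input, so
    containment of the left edge implies containment of the segment.
    """
    seg_starts = boundaries[:-1]
    idx = np.searchsorted(starts, seg_starts, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(len(seg_starts), dtype=bool)
    mask[ok] = ends[idx[ok]] > seg_starts[ok]
    return mask


def partition_regions(inputs: list[RegionSet]) -> PartitionedSegments:
    """Decompose ≥2 region sets into unique overlapping segments.

    The boundary set on each chromosome is the union of all starts and
    ends of all inputs; the segments are the intervals between consecutive
    boundaries that lie inside at least one input, each annotated with the
    labels of the inputs covering it and with boundary-sharing flags.
    """
    if not inputs:
        raise ValueError("partition requires at least one input region set")
    labels = tuple(r.label for r in inputs)
    if len(set(labels)) != len(labels):
        raise ValueError("input region set labels must be unique")
    chrom_order: list[str] = []
    for r in inputs:
        for c in r.df["chrom"].unique():
            if c not in chrom_order:
                chrom_order.append(c)
    rows = []
    for chrom in sorted(chrom_order):
        per_set = []
        bounds: list[np.ndarray] = []
        for r in inputs:
            sub = r.df[r.df["chrom"] == chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            per_set.append((s, e))
            bounds.append(s)
            bounds.append(e)
        boundaries = np.unique(np.concatenate(bounds)) if bounds else np.array([])
        if len(boundaries) < 2:
            continue
        masks = [_member_mask(boundaries, s, e) for s, e in per_set]
        covered = np.logical_or.reduce(masks)
        seg_starts = boundaries[:-1][covered]
        seg_ends = boundaries[1:][covered]
        membership = [frozenset(lab for lab, m in zip(labels, masks) if m[i])
                      for i in np.flatnonzero(covered)]
        # a boundary is shared when the next kept segment starts exactly
        # where this one ends (membership changes inside the union)
        adj_right = np.zeros(len(seg_starts), dtype=bool)
        adj_right[:-1] = seg_ends[:-1] == seg_starts[1:]
        adj_left = np.zeros(len(seg_starts), dtype=bool)
        adj_left[1:] = adj_right[:-1]
        for i in range(len(seg_starts)):
            rows.append((chrom, int(seg_starts[i]), int(seg_ends[i]),
                         membership[i], bool(adj_left[i]), bool(adj_right[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "membership",
                                     "adj_left", "adj_right"])
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return PartitionedSegments(labels=labels, df=df)


def filter_dominant(parts: PartitionedSegments, adjacent_min: int = 10_000,
                    freestanding_min: int = 3_000,
                    label: str = "differential_domains") -> RegionSet:
    """Keep dominant segments: boundary-sharing segments of length ≥
    ``adjacent_min``, free-standing segments of length ≥ ``freestanding_min``.

    The rule is applied per segment, so both members of a short adjacent
    pair can be dropped. Membership annotation survives on the returned
    set's frame as a ``membership`` column.
    """
    df = parts.df
    if len(df) == 0:
        return RegionSet(label=label)
    lengths = (df["end"] - df["start"]).to_numpy()
    adjacent = parts.is_adjacent()
    keep = np.where(adjacent, lengths >= adjacent_min,
                    lengths >= freestanding_min)
    kept = df[keep].reset_index(drop=True)
    out = RegionSet(label=label, df=kept[["chrom", "start", "end"]])
    out.df = out.df.merge(kept[["chrom", "start", "end", "membership"]],
                          on=["chrom", "start", "end"], how="left")
    return out


def membership_strings(regions: RegionSet) -> list[str]:
    """Comma-joined sorted membership labels per region ('' if absent)."""
    if "membership" not in regions.df:
        return [""] * len(regions)
    return [",".join(sorted(m)) if isinstance(m, frozenset) else ""
            for m in regions.df["membership"]]


def write_membership_bed(regions: RegionSet, path) -> None:
    """BED3 + membership string as 4th column."""
    df = regions.df[["chrom", "start", "end"]].copy()
    df["name"] = membership_strings(regions)
    df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")
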