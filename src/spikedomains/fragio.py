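"""Genomic interval containers and text I/O.

All coordinates are BED-standard 0-based half-open at every interface.
Fragments, regions and coverage tracks are carried as pandas DataFrames
with ``chrom``/``start``/``end`` columns for speed; :class:`GenomicInterval`
is the scalar view. Strand is ignored throughout: CUT&RUN fragments and
the broad domains built from them are strand-less.

Spike-in fragments are distinguished from primary-genome fragments purely
by chromosome-name membership in the spike :class:`ChromSizes` — the
common single-file dialect for spike-calibrated experiments, where reads
were mapped to a combined primary+spike reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_COLS = ["chrom", "start", "end"]


class FormatError(ValueError):
    """Malformed on-disk input (bad coordinates, unknown chromosome, ...)."""


class GenomicInterval(NamedTuple):
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length map for one genome.

    ``label`` tags the genome's role in the experiment ("primary" or
    "spike"); it never affects coordinate arithmetic.
    """

    sizes: dict[str, int]
    label: str = "primary"

    def __post_init__(self) -> None:
        if not self.sizes:
            raise FormatError("chromosome sizes are empty")
        for name, length in self.sizes.items():
            if length <= 0:
                raise FormatError(f"non-positive length for {name!r}: {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())


def _empty_bed_frame() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def _as_bed_frame(intervals: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        df = intervals[_BED_COLS].copy()
    else:
        rows = list(intervals)
        if not rows:
            return _empty_bed_frame()
        df = pd.DataFrame(rows, columns=_BED_COLS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.reset_index(drop=True)


def _validate_intervals(df: pd.DataFrame, sizes: ChromSizes | None = None,
                        what: str = "interval") -> None:
    if len(df) == 0:
        return
    if (df["start"] < 0).any():
        raise FormatError(f"negative {what} start")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise FormatError(
            f"{what} end <= start at {bad['chrom']}:{bad['start']}-{bad['end']}")
    if sizes is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise FormatError(f"unknown chromosome {chrom!r}")
            if (sub["end"] > sizes[chrom]).any():
                raise FormatError(
                    f"{what} exceeds length of {chrom} ({sizes[chrom]} bp)")


def _sort_bed(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


@dataclass
class FragmentSet:
    """One sample's mapped paired-end fragments, split by genome of origin."""

    sample_id: str
    target: str
    primary: pd.DataFrame = field(default_factory=_empty_bed_frame)
    spike: pd.DataFrame = field(default_factory=_empty_bed_frame)

    @property
    def spike_count(self) -> int:
        return len(self.spike)

    @property
    def n_primary(self) -> int:
        return len(self.primary)

    @property
    def total_primary_bp(self) -> int:
        if len(self.primary) == 0:
            return 0
        return int((self.primary["end"] - self.primary["start"]).sum())

    def primary_intervals(self) -> Iterator[GenomicInterval]:
        for row in self.primary.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))


@dataclass
class RegionSet:
    """Named, sorted, non-overlapping strand-less intervals (peaks/domains).

    Abutting intervals are allowed (no silent merging): producers that
    coalesce abutting intervals do so explicitly.
    """

    label: str
    df: pd.DataFrame = field(default_factory=_empty_bed_frame)

    def __post_init__(self) -> None:
        self.df = _sort_bed(_as_bed_frame(self.df))
        _validate_intervals(self.df, what="region")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        for _, sub in self.df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise FormatError(f"overlapping regions in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    @property
    def total_bp(self) -> int:
        if len(self.df) == 0:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def read_chrom_sizes(path, label: str = "primary") -> ChromSizes:
    """Read a two-column (name, length) whitespace-delimited sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {raw_len!r}") from None
            if name in sizes:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        raise FormatError(f"{path}: empty chromosome sizes file")
    return ChromSizes(sizes, label=label)


def _read_bed3(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=_BED_COLS,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return _empty_bed_frame()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_fragment_bed(path, primary: ChromSizes, spike: ChromSizes,
                      sample_id: str = "", target: str = "",
                      strict: bool = False) -> FragmentSet:
    """Read a fragment BED and route intervals to primary vs spike genome.

    Chromosomes present in neither genome are skipped with a logged count
    by default; ``strict=True`` raises instead.
    """
    df = _read_bed3(path)
    _validate_intervals(df, what="fragment")
    is_primary = df["chrom"].isin(primary.sizes).to_numpy()
    is_spike = df["chrom"].isin(spike.sizes).to_numpy()
    unknown = ~(is_primary | is_spike)
    if unknown.any():
        if strict:
            bad = df.loc[unknown, "chrom"].iloc[0]
            raise FormatError(f"unknown chromosome {bad!r} in {path}")
        logger.warning("skipped %d fragments on unknown chromosomes in %s",
                       int(unknown.sum()), path)
    prim = df[is_primary].reset_index(drop=True)
    spk = df[is_spike].reset_index(drop=True)
    _validate_intervals(prim, primary, what="fragment")
    _validate_intervals(spk, spike, what="fragment")
    return FragmentSet(sample_id=sample_id or str(path), target=target,
                       primary=_sort_bed(prim), spike=_sort_bed(spk))


def write_fragment_bed(frags: FragmentSet, path) -> None:
    """Write primary then spike fragments as BED3 (tab-delimited, LF)."""
    df = pd.concat([frags.primary, frags.spike], ignore_index=True)
    df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_region_bed(path, label: str | None = None,
                    overlap_policy: str = "error") -> RegionSet:
    """Read a BED3 region file, sorting on read.

    ``overlap_policy``: "error" rejects overlapping input; "merge"
    coalesces overlapping (but not merely abutting) intervals.
    """
    df = _sort_bed(_read_bed3(path))
    _validate_intervals(df, what="region")
    if overlap_policy == "merge":
        df = _merge_frame(df, coalesce_abutting=False)
    return RegionSet(label=label or str(path), df=df)


def write_region_bed(regions: RegionSet, path) -> None:
    regions.df.to_csv(path, sep="\t", header=False, index=False,
                      columns=_BED_COLS, lineterminator="\n")


def _merge_frame(df: pd.DataFrame, coalesce_abutting: bool) -> pd.DataFrame:
    """Coalesce sorted intervals; abutting ones join only when asked."""
    if len(df) == 0:
        return df
    out_chrom, out_start, out_end = [], [], []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joins = s <= cur_e if coalesce_abutting else s < cur_e
            if joins:
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom,
                         "start": np.asarray(out_start, dtype=np.int64),
                         "end": np.asarray(out_end, dtype=np.int64)})


def regions_from_intervals(label: str, intervals: Iterable[tuple]) -> RegionSet:
    """Build a RegionSet from (chrom, start, end) tuples."""
    return RegionSet(label=label, df=_as_bed_frame(intervals))


def write_bedgraph(track, path) -> None:
    """Write a coverage track as 4-column bedGraph (0-based half-open).

    Zero-valued bins are omitted; values are serialized with 6 decimal
    places. Bins must be sorted and disjoint, which `CoverageTrack`
    guarantees by construction.
    """
    df = track.bin_frame()
    df = df[df["value"] != 0]
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6f}\n")


def read_bedgraph(path, sizes: ChromSizes, bin_width: int):
    """Read a bedGraph written by :func:`write_bedgraph` back into a track.

    Each line must cover exactly one bin of the given width (the last bin
    of a chromosome may be clipped). Omitted bins are zero.
    """
    from .normalize import CoverageTrack  # track type lives with calibration

    track = CoverageTrack(sizes=sizes, bin_width=bin_width)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return track
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in sizes:
            raise FormatError(f"unknown chromosome {chrom!r} in {path}")
        starts = sub["start"].to_numpy()
        if (starts % bin_width != 0).any():
            raise FormatError(f"bedGraph line not on a {bin_width} bp bin grid")
        track.values[chrom][starts // bin_width] = sub["value"].to_numpy()
    return track
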