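"""Enriched-region calling and replicate merging.

The caller is a simplified sparse-enrichment caller: candidate blocks are
maximal runs of strictly positive signal on a fine-binned coverage track,
scored by total signal (area under the curve) within the block. Blocks
are kept when their score exceeds the maximum block score of a control
track (IgG), or — with no control — a top-quantile score threshold. This
keeps the core idea of sparse-enrichment peak calling for nuclease
footprinting data, where background regions are genuinely empty; externally
called peak BEDs (e.g. SEACR output) are accepted via
:func:`spikedomains.fragio.read_region_bed` as a first-class alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragio import GenomicInterval, RegionSet, _merge_frame, _sort_bed
from .normalize import CoverageTrack


@dataclass(frozen=True)
class ScoredBlock:
    """A maximal run of nonzero signal with its AUC score and max height."""

    interval: GenomicInterval
    score: float
    max_height: float


def _blocks_one_chrom(chrom: str, vals: np.ndarray, bin_width: int,
                      chrom_len: int, min_width: int) -> list[ScoredBlock]:
    nz = vals > 0
    if not nz.any():
        return []
    padded = np.concatenate([[False], nz, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    run_starts, run_ends = edges[::2], edges[1::2]
    blocks = []
    for b0, b1 in zip(run_starts, run_ends):
        start = int(b0) * bin_width
        end = min(int(b1) * bin_width, chrom_len)
        if end - start < min_width:
            continue
        seg = vals[b0:b1]
        blocks.append(ScoredBlock(GenomicInterval(chrom, start, end),
                                  float(seg.sum()), float(seg.max())))
    return blocks


def signal_blocks(track: CoverageTrack, min_width: int = 1) -> list[ScoredBlock]:
    """All maximal positive-signal runs of a track as scored blocks."""
    out: list[ScoredBlock] = []
    for chrom in track.sizes.chroms:
        out.extend(_blocks_one_chrom(chrom, track.values[chrom],
                                     track.bin_width, track.sizes[chrom],
                                     min_width))
    return out


def call_domains(signal: CoverageTrack, control: CoverageTrack | None = None,
                 threshold_quantile: float = 0.01,
                 min_width: int = 1, label: str = "domains") -> RegionSet:
    """Call enriched regions from a (fine-binned) coverage track.

    With a control, blocks scoring strictly above the control's maximum
    block score are kept. Without one, blocks scoring strictly above the
    (1 - threshold_quantile) quantile of block scores are kept — i.e.
    roughly the top ``threshold_quantile`` fraction of blocks.
    """
    if control is not None and (control.bin_width != signal.bin_width
                                or control.sizes.sizes != signal.sizes.sizes):
        raise ValueError("signal and control must share genome and resolution")
    blocks = signal_blocks(signal, min_width=min_width)
    if not blocks:
        return RegionSet(label=label)
    scores = np.array([b.score for b in blocks])
    if control is not None:
        ctrl_blocks = signal_blocks(control, min_width=min_width)
        threshold = max((b.score for b in ctrl_blocks), default=0.0)
    else:
        if not 0 < threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        threshold = float(np.quantile(scores, 1 - threshold_quantile))
    kept = [b.interval for b, s in zip(blocks, scores) if s > threshold]
    df = pd.DataFrame(kept, columns=["chrom", "start", "end"])
    return RegionSet(label=label, df=df)


def merge_replicates(*replicates: RegionSet, label: str | None = None) -> RegionSet:
    """Union of replicate peak lists with overlapping OR abutting intervals
    coalesced (the merge semantics of interval-union utilities: abutting
    intervals join)."""
    if not replicates:
        raise ValueError("need at least one region set")
    df = pd.concat([r.df for r in replicates], ignore_index=True)
    merged = _merge_frame(_sort_bed(df), coalesce_abutting=True)
    return RegionSet(label=label or "+".join(r.label for r in replicates),
                     df=merged)
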