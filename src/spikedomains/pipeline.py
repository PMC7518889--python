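"""End-to-end orchestration: simulate/load -> calibrate -> call -> merge ->
partition -> filter -> cluster -> quantify, driven by a YAML config.

Every stage output is a pure function of (inputs, parameters, seed);
intermediate files get deterministic names under the output directory and
the JSON run report carries enough provenance (spike factors, region
counts surviving each step, selected k, cluster sizes) to reconstruct the
run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clusterquant, diffregions, domains, fragio, normalize

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class SampleSpec:
    sample_id: str
    target: str
    fragments: Path
    group: str


@dataclass
class PipelineConfig:
    primary_sizes: Path
    spike_sizes: Path
    samples: list[SampleSpec]
    outdir: Path
    bin_width: int = 5000
    call_bin_width: int = 500
    spike_constant: float = 10_000.0
    threshold_quantile: float = 0.01
    adjacent_min: int = 10_000
    freestanding_min: int = 3_000
    k_min: int = 2
    k_max: int = 15
    restarts: int = 25
    seed: int = 1
    control_group: str | None = None  # group used as calling control (IgG)
    params_extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            genome = raw["genome"]
            samples = [SampleSpec(sample_id=s["id"], target=s.get("target", ""),
                                  fragments=Path(s["fragments"]),
                                  group=s.get("group", s["id"]))
                       for s in raw["samples"]]
            params = raw.get("params", {})
            cfg = cls(primary_sizes=Path(genome["primary_sizes"]),
                      spike_sizes=Path(genome["spike_sizes"]),
                      samples=samples, outdir=Path(raw["outdir"]),
                      **{k: v for k, v in params.items()
                         if k in cls.__dataclass_fields__})
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.samples:
            raise ConfigError("no samples configured")
        if self.k_min >= self.k_max:
            raise ConfigError("need k_min < k_max")
        for name in ("bin_width", "call_bin_width", "adjacent_min",
                     "freestanding_min", "spike_constant"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for p in (self.primary_sizes, self.spike_sizes):
            if not Path(p).exists():
                raise ConfigError(f"missing input file: {p}")
        for s in self.samples:
            if not Path(s.fragments).exists():
                raise ConfigError(f"missing fragment BED: {s.fragments}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write intermediates and a JSON report to outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    primary = fragio.read_chrom_sizes(config.primary_sizes, label="primary")
    spike = fragio.read_chrom_sizes(config.spike_sizes, label="spike")

    report: dict = {"samples": {}, "stages": {}}
    frag_sets, scales = {}, {}
    for s in config.samples:
        frags = fragio.read_fragment_bed(s.fragments, primary, spike,
                                         sample_id=s.sample_id, target=s.target)
        scale = normalize.spike_scale_factor(frags.spike_count,
                                             config.spike_constant)
        frag_sets[s.sample_id], scales[s.sample_id] = frags, scale
        report["samples"][s.sample_id] = {
            "group": s.group, "target": s.target,
            "n_primary_fragments": frags.n_primary,
            "n_spike_fragments": frags.spike_count,
            "spike_factor": scale.factor,
        }

    # control track (optional) = pooled coverage of the control group
    control_track = None
    if config.control_group is not None:
        ctrl_ids = [s.sample_id for s in config.samples
                    if s.group == config.control_group]
        if not ctrl_ids:
            raise ConfigError(f"control group {config.control_group!r} empty")
        tracks = [normalize.binned_coverage(frag_sets[i], primary,
                                            config.call_bin_width)
                  for i in ctrl_ids]
        control_track = tracks[0]
        for t in tracks[1:]:
            for c in control_track.values:
                control_track.values[c] += t.values[c]

    # per-sample domain calls, then replicate merge per group
    calls, group_members = {}, {}
    for s in config.samples:
        if config.control_group is not None and s.group == config.control_group:
            continue
        track = normalize.binned_coverage(frag_sets[s.sample_id], primary,
                                          config.call_bin_width)
        called = domains.call_domains(track, control=control_track,
                                      threshold_quantile=config.threshold_quantile,
                                      label=s.sample_id)
        calls[s.sample_id] = called
        group_members.setdefault(s.group, []).append(s.sample_id)
        fragio.write_region_bed(called, out / f"call_{s.sample_id}.bed")
    report["stages"]["called_per_sample"] = {k: len(v) for k, v in calls.items()}

    merged = {}
    for group, members in group_members.items():
        merged[group] = domains.merge_replicates(
            *[calls[m] for m in members], label=group)
        fragio.write_region_bed(merged[group], out / f"merged_{group}.bed")
    report["stages"]["merged_per_group"] = {g: len(r) for g, r in merged.items()}

    parts = diffregions.partition_regions(list(merged.values()))
    report["stages"]["partitioned_segments"] = len(parts)
    diff = diffregions.filter_dominant(parts, config.adjacent_min,
                                       config.freestanding_min)
    diffregions.write_membership_bed(diff, out / "differential_domains.bed")
    report["stages"]["differential_domains"] = len(diff)

    quant_ids = sorted(frag_sets) if config.control_group is None else \
        sorted(i for i in frag_sets
               if report["samples"][i]["group"] != config.control_group)
    matrix = clusterquant.signal_matrix(
        diff, [(frag_sets[i], scales[i]) for i in quant_ids])
    matrix.to_frame().to_csv(out / "signal_matrix.tsv", sep="\t")

    assignment = clusterquant.select_k_knee(
        matrix, k_min=config.k_min,
        k_max=min(config.k_max, max(config.k_min + 1, len(diff) - 1)),
        seed=config.seed, restarts=config.restarts)
    sizes = {int(c): int((assignment.labels == c).sum())
             for c in range(1, assignment.k + 1)}
    clusters_df = diff.df[["chrom", "start", "end"]].copy()
    clusters_df["cluster"] = assignment.labels
    clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    report["stages"]["selected_k"] = assignment.selected_k
    report["stages"]["cluster_sizes"] = sizes
    report["stages"]["withinss_by_k"] = {
        str(k): v for k, v in sorted(assignment.withinss_by_k.items())}

    raw = clusterquant.signal_matrix(
        diff, [(frag_sets[i], None) for i in quant_ids], spike_scale=False)
    fpk = clusterquant.fpk_scale(
        raw, constants={i: scales[i].factor for i in quant_ids})
    stats = clusterquant.cluster_region_stats(fpk, assignment)
    stats.to_csv(out / "cluster_stats.tsv", sep="\t", index=False)
    report["stages"]["cluster_stats"] = stats.to_dict(orient="records")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d differential domains, k=%d",
                len(diff), assignment.selected_k)
    return report
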