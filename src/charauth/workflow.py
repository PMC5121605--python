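"""End-to-end orchestration: simulate/ingest -> trim -> map -> filter ->
damage -> bleed, with a deterministic JSON/TSV report bundle.

The pipeline is a pure function of (inputs, config): rerunning with the same
seed produces byte-identical outputs. Each stage logs counts in and out so
filter behaviour stays auditable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from typing import Optional, Sequence

import pandas as pd

from . import bleed_detect, damage_profile, mapping_filter, preprocess
from .bleed_detect import IndexAssayConfig, IndexRegistry
from .preprocess import TrimPolicy
from .synthetic_data import CONTAMINANT_ID, GenomeSet, PoolConfig, simulate_pool

logger = logging.getLogger("charauth.workflow")


@dataclasses.dataclass
class RunConfig:
    """Inputs, stage toggles and parameters for one pipeline run."""

    pool: PoolConfig
    genomes: GenomeSet
    out_dir: Optional[str] = None
    map_genome_ids: Optional[Sequence[str]] = None  # default: all but contaminant
    trim_policy: TrimPolicy = dataclasses.field(default_factory=TrimPolicy)
    assay: IndexAssayConfig = dataclasses.field(default_factory=IndexAssayConfig)
    mapq_threshold: int = 25
    seed_length: int = 16
    damage_window: int = 25
    min_terminal: float = 0.05
    decay_ratio: float = 2.0
    min_opportunities: int = 200
    do_damage: bool = True
    do_bleed: bool = True

    def target_genomes(self) -> list[str]:
        if self.map_genome_ids is not None:
            return list(self.map_genome_ids)
        return [g for g in self.genomes.ids if g != CONTAMINANT_ID]


def _log_stage(stage: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info(
        "stage=%s in=%d out=%d wall_s=%.2f", stage, n_in, n_out, time.time() - t0
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage and return the report bundle.

    The bundle holds the mapping summary table, per-(library, genome) damage
    profiles and signature calls, and the bleed report computed on raw reads
    partitioned by membership in the post-filter alignment set.
    """
    t0 = time.time()
    reads_by_library, truth = simulate_pool(config.pool, config.genomes)
    n_reads = sum(len(v) for v in reads_by_library.values())
    _log_stage("simulate", 0, n_reads, t0)

    t0 = time.time()
    trimmed: dict[str, list[preprocess.ReadRecord]] = {}
    for lib in sorted(reads_by_library):
        kept = []
        for read in reads_by_library[lib]:
            tr = preprocess.trim_read(read, config.trim_policy)
            if tr is not None:
                kept.append(tr)
        trimmed[lib] = kept
    n_trimmed = sum(len(v) for v in trimmed.values())
    _log_stage("trim", n_reads, n_trimmed, t0)

    t0 = time.time()
    target_ids = config.target_genomes()
    map_genomes = GenomeSet(
        [(gid, config.genomes[gid]) for gid in target_ids]
    )
    all_trimmed = [r for lib in sorted(trimmed) for r in trimmed[lib]]
    alignments = mapping_filter.toy_map(
        all_trimmed, map_genomes, k=config.seed_length
    )
    _log_stage("toy_map", n_trimmed, len(alignments), t0)

    t0 = time.time()
    raw_totals = {lib: max(1, len(reads_by_library[lib])) for lib in reads_by_library}
    summary = mapping_filter.mapping_rate_table(
        alignments, raw_totals, genome_ids=target_ids,
        mapq_threshold=config.mapq_threshold,
    )
    filtered: dict[tuple[str, str], list[mapping_filter.Alignment]] = {}
    groups: dict[tuple[str, str], list[mapping_filter.Alignment]] = {}
    for a in alignments:
        groups.setdefault((a.library, a.genome_id), []).append(a)
    for key, group in groups.items():
        kept = mapping_filter.filter_mapq(group, config.mapq_threshold)
        kept, _ = mapping_filter.remove_duplicates(kept)
        filtered[key] = kept
    n_filtered = sum(len(v) for v in filtered.values())
    _log_stage("filter", len(alignments), n_filtered, t0)

    bundle: dict = {
        "config_seed": config.pool.seed,
        "n_raw_reads": n_reads,
        "n_trimmed_reads": n_trimmed,
        "n_alignments": len(alignments),
        "n_filtered_alignments": n_filtered,
        "mapping_summary": summary,
        "truth": truth,
    }

    if config.do_damage:
        t0 = time.time()
        damage_rows = []
        for (lib, gid) in sorted(filtered):
            group = filtered[(lib, gid)]
            if not group:
                continue
            profile = damage_profile.misincorporation_profile(
                group, config.genomes, window=config.damage_window
            )
            flag, rationale = damage_profile.has_damage_signature(
                profile,
                min_terminal=config.min_terminal,
                decay_ratio=config.decay_ratio,
                min_opportunities=config.min_opportunities,
            )
            damage_rows.append(
                {
                    "library": lib,
                    "genome_id": gid,
                    "n_alignments": profile.n_alignments,
                    "ct5_1": profile.ct5[0],
                    "ga3_1": profile.ga3[0],
                    "damage_signature": flag,
                    "rationale": rationale,
                }
            )
        bundle["damage"] = pd.DataFrame(
            damage_rows,
            columns=[
                "library",
                "genome_id",
                "n_alignments",
                "ct5_1",
                "ga3_1",
                "damage_signature",
                "rationale",
            ],
        )
        _log_stage("damage", n_filtered, len(damage_rows), t0)

    if config.do_bleed:
        t0 = time.time()
        registry = IndexRegistry.from_samples(config.pool.samples)
        mapped_ids = {
            a.read_id for group in filtered.values() for a in group
        }
        counts = bleed_detect.count_indexes(
            reads_by_library,
            lambda rid: "mapped" if rid in mapped_ids else "background",
            config.assay,
            registry,
        )
        report = bleed_detect.build_bleed_report(counts, registry=registry)
        bundle["index_counts"] = counts
        bundle["bleed_report"] = report
        try:
            bundle["hop_rate"] = bleed_detect.estimate_hop_rate(counts)
        except ValueError:
            bundle["hop_rate"] = None
        _log_stage("bleed", n_reads, len(report.per_library), t0)

    if config.out_dir is not None:
        render_report(bundle, config.out_dir)
    return bundle


def _round_floats(obj, digits: int = 6):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, digits) for v in obj]
    return obj


def render_report(bundle: dict, out_dir) -> None:
    """Write the bundle as TSV tables plus one aggregated JSON summary.

    Column order and float precision are fixed so reruns are byte-identical.
    Raises when a required section is missing.
    """
    for required in ("mapping_summary", "truth"):
        if required not in bundle:
            raise ValueError(f"incomplete bundle: missing section {required!r}")
    os.makedirs(out_dir, exist_ok=True)
    bundle["mapping_summary"].to_csv(
        os.path.join(out_dir, "mapping_summary.tsv"),
        sep="\t", index=False, float_format="%.6f",
    )
    bundle["truth"].to_csv(
        os.path.join(out_dir, "truth.tsv"), sep="\t", index=False
    )
    summary: dict = {
        "seed": bundle["config_seed"],
        "n_raw_reads": bundle["n_raw_reads"],
        "n_trimmed_reads": bundle["n_trimmed_reads"],
        "n_alignments": bundle["n_alignments"],
        "n_filtered_alignments": bundle["n_filtered_alignments"],
        "mapping_summary": bundle["mapping_summary"].to_dict(orient="records"),
    }
    if "damage" in bundle:
        bundle["damage"].to_csv(
            os.path.join(out_dir, "damage.tsv"),
            sep="\t", index=False, float_format="%.6f",
        )
        summary["damage"] = bundle["damage"].to_dict(orient="records")
    if "bleed_report" in bundle:
        report = bundle["bleed_report"]
        report.per_library.to_csv(
            os.path.join(out_dir, "bleed_per_library.tsv"),
            sep="\t", index=False, float_format="%.6f",
        )
        summary["bleed"] = report.to_json_dict()
        hop = bundle.get("hop_rate")
        if hop is not None:
            summary["hop_rate"] = {
                "rate": hop.rate,
                "ci_low": hop.ci_low,
                "ci_high": hop.ci_high,
                "foreign": hop.foreign,
                "readable": hop.readable,
            }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True,
                  allow_nan=True)
        fh.write("\n")
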