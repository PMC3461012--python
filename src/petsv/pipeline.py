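"""End-to-end pipeline: classify -> dedup -> cluster -> filter -> call ->
supercluster -> (optional) amplicon, with stage counts and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from petsv._version import __version__ as _version
from petsv.amplicon import (AmpliconGraph, CoverageTrack, GenomeGraph,
                            build_genome_graph, coverage_track, grow_amplicons,
                            segment_contigs)
from petsv.clustering import DPETCluster, cluster_dpets, filter_clusters
from petsv.errors import InputError
from petsv.pet_io import LibraryConfig, as_frame, classify_library, deduplicate, split_by_status
from petsv.supercluster import Supercluster, build_superclusters, classify_complexity
from petsv.sv_calls import SVCall, pair_and_call


def infer_chrom_lengths(frame: pd.DataFrame, pad: int = 1_000) -> dict[str, int]:
    """Fallback chromosome lengths from the largest mapped coordinate."""
    lengths: dict[str, int] = {}
    for side in ("5", "3"):
        grouped = frame.groupby(f"chrom{side}")[f"end{side}"].max()
        for chrom, end in grouped.items():
            lengths[chrom] = max(lengths.get(chrom, 0), int(end) + pad)
    return dict(sorted(lengths.items()))


@dataclass
class PipelineResult:
    """All pipeline artifacts plus the Table-style stage count summary."""

    config: LibraryConfig
    pets: pd.DataFrame
    clusters: list[DPETCluster]
    filtered_clusters: list[DPETCluster]
    calls: list[SVCall]
    superclusters: list[Supercluster]
    coverage: Optional[CoverageTrack] = None
    genome_graph: Optional[GenomeGraph] = None
    amplicons: Optional[list[AmpliconGraph]] = None
    stage_counts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        c = self.stage_counts
        return pd.DataFrame([{
            "library": self.config.name,
            "total_nr_pets": c["total_nr_pets"],
            "cpet": c["cpet"],
            "pct_cpet": round(100 * c["cpet"] / c["total_nr_pets"], 1) if c["total_nr_pets"] else 0,
            "dpet": c["dpet"],
            "pct_dpet": round(100 * c["dpet"] / c["total_nr_pets"], 1) if c["total_nr_pets"] else 0,
            "dpet_singletons": c["dpet_singletons"],
            "clusters_ge_cutoff": c["clusters_ge_cutoff"],
            "dpets_in_clusters": c["dpets_in_clusters"],
            "sv_calls": c["sv_calls"],
        }])


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def run_pipeline(pets, config: LibraryConfig, *,
                 chrom_lengths: Optional[Mapping[str, int]] = None,
                 min_cluster: Optional[int] = None,
                 cluster_window: Optional[int] = None,
                 compute_coverage: bool = True,
                 compute_amplicons: bool = False,
                 coverage_bin: int = 1_000,
                 input_path=None,
                 command: Optional[str] = None) -> PipelineResult:
    """Run the full discovery chain on one PET library.

    Stage identity: total non-redundant PETs = concordant + discordant.
    When ``compute_coverage`` is on (and the cPET depth allows), cut-and-paste
    insertion sub-types are corroborated by the concordant-tag track; with
    ``compute_amplicons`` the genome graph and amplicon growth run as well.
    """
    if min_cluster is None:
        min_cluster = config.cluster_count_min

    frame = as_frame(pets)
    raw_count = len(frame)
    frame = classify_library(frame, config)
    frame = deduplicate(frame)
    cpets, dpets = split_by_status(frame)
    total = len(frame)

    coverage = None
    if compute_coverage and len(cpets):
        if chrom_lengths is None:
            chrom_lengths = infer_chrom_lengths(frame)
        try:
            coverage = coverage_track(cpets, chrom_lengths, bin_size=coverage_bin)
        except InputError:
            coverage = None  # too sparse to normalise; proceed without

    clusters = cluster_dpets(dpets, config, window=cluster_window)
    filtered = filter_clusters(clusters, min_cluster)
    superclusters = build_superclusters(filtered, config)
    calls = pair_and_call(filtered, config, coverage=coverage)
    calls = classify_complexity(calls, superclusters)

    genome_graph = None
    amplicons = None
    if compute_amplicons:
        if coverage is None:
            raise InputError("amplicon reconstruction needs a coverage track (concordant PETs)")
        contigs = segment_contigs(filtered, coverage, chrom_lengths)
        genome_graph = build_genome_graph(contigs, filtered, cpets)
        amplicons = grow_amplicons(genome_graph)

    stage_counts = {
        "input_pets": raw_count,
        "total_nr_pets": total,
        "duplicates_removed": raw_count - total,
        "cpet": len(cpets),
        "dpet": len(dpets),
        "dpet_singletons": len(dpets) - sum(c.count for c in clusters if c.count > 1),
        "n_clusters": len(clusters),
        "clusters_ge_cutoff": len(filtered),
        "dpets_in_clusters": sum(c.count for c in filtered),
        "n_superclusters": len(superclusters),
        "sv_calls": len(calls),
        "isolated_calls": sum(1 for c in calls if c.complexity == "isolated"),
        "complex_calls": sum(1 for c in calls if c.complexity == "complex"),
    }
    assert stage_counts["cpet"] + stage_counts["dpet"] == stage_counts["total_nr_pets"]

    manifest = {
        "tool": "petsv",
        "version": _version,
        "command": command,
        "library_config": dataclasses.asdict(config),
        "parameters": {
            "min_cluster": min_cluster,
            "cluster_window": cluster_window,
            "coverage_bin": coverage_bin,
            "compute_coverage": compute_coverage,
            "compute_amplicons": compute_amplicons,
        },
        "input": {
            "path": str(input_path) if input_path is not None else None,
            "sha256": _sha256(input_path) if input_path is not None else None,
            "n_records": raw_count,
        },
        "stage_counts": stage_counts,
    }
    return PipelineResult(
        config=config, pets=frame, clusters=clusters, filtered_clusters=filtered,
        calls=calls, superclusters=superclusters, coverage=coverage,
        genome_graph=genome_graph, amplicons=amplicons,
        stage_counts=stage_counts, manifest=manifest,
    )


def write_manifest(result: PipelineResult, path) -> None:
    with open(path, "wt") as out:
        json.dump(result.manifest, out, indent=2, sort_keys=True)
        out.write("\n")
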