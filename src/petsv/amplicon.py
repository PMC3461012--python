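"""Copy number from physical coverage and fusion-point-guided concatenation.

Concordant fragments tile the reference; per-bin counts of overlapping
fragments give a physical coverage track and, normalised to the genome-wide
median (taken as the baseline ploidy), a copy-number estimate.  The reference
is segmented into contigs at cluster-predicted breakpoints and at boundaries
of coverage-free runs; contigs consecutive on the reference are connected by
reference edges where concordant fragments straddle the junction, and dPET
clusters add fusion edges weighted by their count.  Amplicon graphs grow from
the heaviest unused fusion edge through amplified neighbours (copy number
above the baseline) until no contig can be added; graphs of more than two
contigs are reported.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from petsv.clustering import DPETCluster
from petsv.errors import InputError, InvariantError
from petsv.pet_io import as_frame

DEFAULT_BIN_SIZE = 1_000
BASELINE_PLOIDY = 2
#: strict threshold: a contig is amplified iff copy number is greater than this
AMPLIFIED_MIN_CN = 2.0


# ---------------------------------------------------------------------------
# coverage / copy number


@dataclass
class CoverageTrack:
    """Binned physical-coverage depth and derived copy number per chromosome.

    ``depth`` counts concordant fragments whose span overlaps each bin (the
    physical, clone-style coverage).  ``tag_depth`` counts concordant tag
    starts per bin: a short excised segment is still spanned concordantly by
    large fragments, so its loss shows up in the tag track, not the fragment
    track.
    """

    bin_size: int
    depth: dict[str, np.ndarray]
    median_depth: float
    tag_depth: dict[str, np.ndarray] = None
    median_tag_depth: float = 0.0
    baseline_ploidy: int = BASELINE_PLOIDY

    def copy_number(self, chrom: str) -> np.ndarray:
        return self.depth[chrom] / self.median_depth * self.baseline_ploidy

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean binned depth over [start, end), weighting bins by overlap."""
        if end <= start:
            raise InputError("empty interval")
        bins = self.depth[chrom]
        lo = start // self.bin_size
        hi = min((end - 1) // self.bin_size, len(bins) - 1)
        weights = np.full(hi - lo + 1, float(self.bin_size))
        weights[0] -= start - lo * self.bin_size
        weights[-1] -= (hi + 1) * self.bin_size - end
        if weights[-1] <= 0:  # single-bin interval shorter than a bin
            weights[-1] = end - start
        segment = bins[lo:hi + 1]
        return float(np.average(segment, weights=weights))

    def mean_copy_number(self, chrom: str, start: int, end: int) -> float:
        return self.mean_depth(chrom, start, end) / self.median_depth * self.baseline_ploidy

    def mean_tag_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean concordant-tag count over the bins fully inside [start, end)
        (falls back to the overlapping bins when none fits)."""
        if self.tag_depth is None:
            raise InputError("coverage track carries no tag-depth data")
        bins = self.tag_depth[chrom]
        lo = -(-start // self.bin_size)  # first bin fully inside
        hi = end // self.bin_size        # one past last bin fully inside
        if hi <= lo:
            lo, hi = start // self.bin_size, end // self.bin_size + 1
        segment = bins[lo:min(hi, len(bins))]
        return float(segment.mean()) if segment.size else 0.0

    def to_bedgraph(self, path) -> None:
        with open(path, "wt") as out:
            out.write("track type=bedGraph name=petsv_physical_coverage\n")
            for chrom, bins in self.depth.items():
                for i, value in enumerate(bins):
                    out.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{value:g}\n")


def coverage_track(cpets, chrom_lengths: Mapping[str, int],
                   bin_size: int = DEFAULT_BIN_SIZE,
                   baseline_ploidy: int = BASELINE_PLOIDY) -> CoverageTrack:
    """Per-bin count of concordant fragments overlapping each bin.

    Copy number is depth divided by the genome-wide median depth times the
    baseline ploidy (the median is robust to focal amplification).
    """
    if bin_size <= 0:
        raise InputError("bin_size must be positive")
    frame = as_frame(cpets)
    if "status" in frame.columns:
        frame = frame[frame["status"] == "concordant"]
    depth: dict[str, np.ndarray] = {}
    tag_depth: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        diff = np.zeros(n_bins + 1)
        tags = np.zeros(n_bins)
        sub = frame[frame["chrom5"] == chrom]
        if len(sub):
            lo = np.minimum(sub["start5"].to_numpy(), sub["start3"].to_numpy())
            hi = np.maximum(sub["end5"].to_numpy(), sub["end3"].to_numpy())
            first = np.clip(lo // bin_size, 0, n_bins - 1)
            last = np.clip((hi - 1) // bin_size, 0, n_bins - 1)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            tag_bins = np.concatenate([
                sub["start5"].to_numpy() // bin_size,
                sub["start3"].to_numpy() // bin_size,
            ])
            np.add.at(tags, np.clip(tag_bins, 0, n_bins - 1), 1)
        depth[chrom] = np.cumsum(diff[:-1])
        tag_depth[chrom] = tags
    all_bins = np.concatenate(list(depth.values())) if depth else np.array([])
    median = float(np.median(all_bins)) if all_bins.size else 0.0
    if median == 0:
        raise InputError("genome-wide median physical depth is zero; cannot normalise copy number")
    all_tag_bins = np.concatenate(list(tag_depth.values()))
    return CoverageTrack(bin_size=bin_size, depth=depth, median_depth=median,
                         tag_depth=tag_depth,
                         median_tag_depth=float(np.median(all_tag_bins)),
                         baseline_ploidy=baseline_ploidy)


# ---------------------------------------------------------------------------
# contig segmentation


@dataclass(frozen=True)
class Contig:
    """Reference segment between breakpoints, with mean copy number."""

    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError("contig must satisfy start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def amplified(self) -> bool:
        return self.copy_number > AMPLIFIED_MIN_CN

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end} (CN {self.copy_number:.1f})"


def _zero_runs(bins: np.ndarray, bin_size: int) -> list[tuple[int, int]]:
    """Boundaries of maximal zero-depth runs spanning at least one full bin."""
    zero = bins == 0
    runs = []
    i = 0
    while i < len(zero):
        if zero[i]:
            j = i
            while j < len(zero) and zero[j]:
                j += 1
            runs.append((i * bin_size, j * bin_size))
            i = j
        else:
            i += 1
    return runs


def segment_contigs(clusters: Sequence[DPETCluster], track: CoverageTrack,
                    chrom_lengths: Mapping[str, int]) -> list[Contig]:
    """Cut each chromosome at predicted breakpoints and at the boundaries of
    physical-coverage-free runs; attach mean copy number per contig."""
    cuts: dict[str, set[int]] = {chrom: {0, length} for chrom, length in chrom_lengths.items()}
    for cluster in clusters:
        for chrom, bp in (cluster.breakpoint5(), cluster.breakpoint3()):
            if chrom in cuts:
                cuts[chrom].add(int(np.clip(bp, 0, chrom_lengths[chrom])))
    for chrom, length in chrom_lengths.items():
        for start, end in _zero_runs(track.depth[chrom], track.bin_size):
            cuts[chrom].add(min(start, length))
            cuts[chrom].add(min(end, length))
    contigs: list[Contig] = []
    for chrom in chrom_lengths:
        positions = sorted(cuts[chrom])
        for start, end in zip(positions, positions[1:]):
            if end > start:
                contigs.append(Contig(chrom, start, end,
                                      track.mean_copy_number(chrom, start, end)))
    return contigs


# ---------------------------------------------------------------------------
# genome graph


@dataclass(frozen=True)
class DPETEdge:
    """Fusion edge between two contigs, weighted by cluster size.

    ``end_u`` / ``end_v`` record which contig end fuses ('head' = low
    coordinate, 'tail' = high coordinate), from the anchor strands.
    """

    u: int
    v: int
    weight: int
    cluster_id: str
    end_u: str
    end_v: str


@dataclass
class GenomeGraph:
    """Contigs connected by reference edges and weighted dPET fusion edges."""

    contigs: list[Contig]
    graph: nx.MultiGraph  # nodes: contig indices; edges tagged kind=reference|dpet
    dpet_edges: list[DPETEdge] = field(default_factory=list)

    def reference_neighbors(self, node: int) -> list[int]:
        return [v for _, v, data in self.graph.edges(node, data=True) if data["kind"] == "reference"]


def _contig_index(contigs: Sequence[Contig], chrom: str, bp: int, ext: str) -> int:
    """Contig containing breakpoint ``bp``; an 'L'-extending anchor fuses at the
    right end of its contig (bp in (start, end]), an 'R' anchor at the left
    end (bp in [start, end))."""
    candidates = [i for i, c in enumerate(contigs) if c.chrom == chrom]
    starts = [contigs[i].start for i in candidates]
    k = bisect_right(starts, bp if ext == "R" else bp - 1) - 1
    if k < 0:
        raise InvariantError(f"breakpoint {chrom}:{bp} falls before all contigs")
    idx = candidates[k]
    if not (contigs[idx].start <= bp <= contigs[idx].end):
        raise InvariantError(f"breakpoint {chrom}:{bp} outside all contigs")
    return idx


def build_genome_graph(contigs: Sequence[Contig], clusters: Sequence[DPETCluster],
                       cpets) -> GenomeGraph:
    """Connect contigs by reference edges (where concordant fragments straddle
    the junction) and one dPET edge per cluster (weight = cluster size)."""
    frame = as_frame(cpets)
    if "status" in frame.columns:
        frame = frame[frame["status"] == "concordant"]
    graph = nx.MultiGraph()
    contigs = list(contigs)
    for i, contig in enumerate(contigs):
        graph.add_node(i, contig=contig)

    # reference edges between reference-consecutive contigs with straddling cPETs
    spans_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in frame.groupby("chrom5"):
        lo = np.minimum(sub["start5"].to_numpy(), sub["start3"].to_numpy())
        hi = np.maximum(sub["end5"].to_numpy(), sub["end3"].to_numpy())
        spans_by_chrom[chrom] = (lo, hi)
    for i, left in enumerate(contigs):
        for j, right in enumerate(contigs):
            if j <= i or left.chrom != right.chrom or left.end != right.start:
                continue
            junction = left.end
            lo, hi = spans_by_chrom.get(left.chrom, (np.array([]), np.array([])))
            support = int(np.sum((lo < junction) & (hi > junction)))
            if support > 0:
                graph.add_edge(i, j, kind="reference", support=support)

    gg = GenomeGraph(contigs=contigs, graph=graph)
    for cluster in clusters:
        ext5 = cluster.anchor5.extends()
        ext3 = cluster.anchor3.extends()
        u = _contig_index(contigs, cluster.chrom5, cluster.predicted_bp5, ext5)
        v = _contig_index(contigs, cluster.chrom3, cluster.predicted_bp3, ext3)
        edge = DPETEdge(
            u=u, v=v, weight=cluster.count, cluster_id=cluster.id,
            end_u="tail" if ext5 == "L" else "head",
            end_v="head" if ext3 == "R" else "tail",
        )
        gg.dpet_edges.append(edge)
        graph.add_edge(u, v, kind="dpet", weight=edge.weight,
                       cluster_id=cluster.id, end_u=edge.end_u, end_v=edge.end_v)
    return gg


# ---------------------------------------------------------------------------
# amplicon growth


@dataclass
class AmpliconGraph:
    """A locally amplified rearrangement unit grown from one fusion edge."""

    id: str
    seed_edge: DPETEdge
    nodes: tuple[int, ...]
    dpet_edges: tuple[DPETEdge, ...]
    graph: nx.MultiGraph

    @property
    def n_contigs(self) -> int:
        return len(self.nodes)


def _edge_sort_key(contigs: Sequence[Contig], edge: DPETEdge):
    cu, cv = contigs[edge.u], contigs[edge.v]
    return (-edge.weight, cu.chrom, cu.start, cv.chrom, cv.start, edge.cluster_id)


def grow_amplicons(genome_graph: GenomeGraph,
                   amplified_min_cn: float = AMPLIFIED_MIN_CN,
                   min_contigs: int = 3) -> list[AmpliconGraph]:
    """Fusion-point-guided concatenation of amplified contigs.

    Repeatedly seed from the highest-weight unused dPET edge (its two contigs
    join unconditionally), then add neighbours through both reference and dPET
    edges as long as the neighbour is amplified (copy number strictly above
    ``amplified_min_cn``), to a fixpoint.  All dPET edges internal to the
    grown node set are marked used; each dPET edge belongs to at most one
    amplicon graph.  Graphs with fewer than ``min_contigs`` contigs are
    discarded (their edges stay used).
    """
    contigs = genome_graph.contigs
    graph = genome_graph.graph
    unused = sorted(genome_graph.dpet_edges, key=lambda e: _edge_sort_key(contigs, e))
    used_ids: set[str] = set()
    amplicons: list[AmpliconGraph] = []
    serial = 0
    for seed in unused:
        if seed.cluster_id in used_ids:
            continue
        nodes = {seed.u, seed.v}
        frontier = [seed.u, seed.v]
        while frontier:
            nxt = []
            for node in frontier:
                for neighbor in graph.neighbors(node):
                    if neighbor in nodes:
                        continue
                    if contigs[neighbor].copy_number > amplified_min_cn:
                        nodes.add(neighbor)
                        nxt.append(neighbor)
            frontier = nxt
        member_edges = tuple(
            e for e in genome_graph.dpet_edges
            if e.cluster_id not in used_ids and e.u in nodes and e.v in nodes
        )
        used_ids.update(e.cluster_id for e in member_edges)
        if len(nodes) >= min_contigs:
            serial += 1
            amplicons.append(AmpliconGraph(
                id=f"A{serial:04d}",
                seed_edge=seed,
                nodes=tuple(sorted(nodes)),
                dpet_edges=member_edges,
                graph=graph.subgraph(nodes).copy(),
            ))
    return amplicons


# ---------------------------------------------------------------------------
# exports


def contigs_to_bed(contigs: Sequence[Contig], path) -> None:
    with open(path, "wt") as out:
        for k, c in enumerate(contigs, start=1):
            out.write(f"{c.chrom}\t{c.start}\t{c.end}\tcontig{k}\t{c.copy_number:.2f}\n")


def graph_to_graphml(genome_graph: GenomeGraph, path) -> None:
    export = nx.MultiGraph()
    for node, data in genome_graph.graph.nodes(data=True):
        c = data["contig"]
        export.add_node(node, chrom=c.chrom, start=c.start, end=c.end,
                        copy_number=round(c.copy_number, 3), amplified=c.amplified)
    for u, v, data in genome_graph.graph.edges(data=True):
        attrs = {k: v2 for k, v2 in data.items() if v2 is not None}
        export.add_edge(u, v, **attrs)
    nx.write_graphml(export, path)


def _display_length(contig: Contig, scale: int) -> float:
    # box length conventions: contig length / scale, clipped into [0.1, 6]
    return float(min(max(contig.length / scale, 0.1), 6.0))


def amplicon_to_dot(amplicon: AmpliconGraph, contigs: Sequence[Contig], path,
                    scale: int = 100_000) -> None:
    """Rendering-ready dot dump: box length from contig length, border width
    from copy number, dashed weighted fusion edges, solid reference edges."""
    lines = [f"graph {amplicon.id} {{", "  node [shape=box];"]
    for node in amplicon.nodes:
        c = contigs[node]
        lines.append(
            f'  n{node} [label="{c.chrom}:{c.start // 1000}k-{c.end // 1000}k\\nCN {c.copy_number:.1f}" '
            f"width={_display_length(c, scale):.2f} penwidth={max(c.copy_number / 2, 0.5):.2f}];"
        )
    for u, v, data in amplicon.graph.edges(data=True):
        if data["kind"] == "reference":
            lines.append(f"  n{u} -- n{v} [style=bold];")
        else:
            lines.append(f'  n{u} -- n{v} [style=dashed penwidth={max(data["weight"] / 10, 0.5):.2f} '
                         f'label="{data["weight"]}"];')
    lines.append("}")
    with open(path, "wt") as out:
        out.write("\n".join(lines) + "\n")
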