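"""Copy number from physical coverage and amplicon graph reconstruction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import cluster_for_fusion, make_pet
from petsv.amplicon import (
    AMPLIFIED_MIN_CN,
    Contig,
    DPETEdge,
    GenomeGraph,
    build_genome_graph,
    coverage_track,
    grow_amplicons,
    segment_contigs,
)
from petsv.errors import InputError, InvariantError
from petsv.pet_io import records_to_frame


def _cpet_frame(spans):
    """Concordant PETs with given (chrom, start, end) fragment footprints."""
    return records_to_frame([
        make_pet(f"c{k}", c5=chrom, s5=start, c3=chrom, s3=end - 25, status="concordant")
        for k, (chrom, start, end) in enumerate(spans)
    ])


def _tiled_spans(chrom, lo, hi, frag=10_000, layers=4):
    """Abutting fragment layers tiling [lo, hi) at uniform depth ``layers``."""
    spans = []
    for layer in range(layers):
        offset = layer * frag // layers
        spans.extend((chrom, s, s + frag) for s in range(lo + offset, hi - frag + 1, frag))
        spans.append((chrom, hi - frag, hi))  # end-aligned closer
    return spans


def _uniform_coverage(chrom="chr1", length=100_000, depth=4, frag=10_000):
    return _cpet_frame(_tiled_spans(chrom, 0, length, frag, depth))


class TestCoverageTrack:
    def test_uniform_depth_normalises_to_baseline_ploidy(self):
        frame = _cpet_frame([("chr1", i * 1_000, i * 1_000 + 10_000) for i in range(90)])
        track = coverage_track(frame, {"chr1": 100_000}, bin_size=1_000)
        mid = track.copy_number("chr1")[20:80]
        assert np.allclose(mid, 2.0)

    def test_copy_number_is_linear_in_depth(self):
        # 4 abutting tilings genome-wide plus 6 more over one region: that
        # region sits at 2.5x the median depth, so copy number 5
        genome_tile = [("chr1", s, s + 10_000) for s in range(0, 100_000, 10_000)]
        region_tile = [("chr1", s, s + 10_000) for s in range(40_000, 60_000, 10_000)]
        spans = genome_tile * 4 + region_tile * 6
        track = coverage_track(_cpet_frame(spans), {"chr1": 100_000}, bin_size=1_000)
        cn = track.copy_number("chr1")
        assert track.mean_copy_number("chr1", 40_000, 60_000) == pytest.approx(5.0)
        assert np.allclose(cn[20:35], 2.0)

    def test_zero_median_rejected(self):
        with pytest.raises(InputError):
            coverage_track(_cpet_frame([]), {"chr1": 10_000})

    def test_tag_depth_counts_tag_starts(self):
        frame = _cpet_frame([("chr1", 1_000, 11_000)])
        track = coverage_track(frame, {"chr1": 20_000}, bin_size=1_000)
        assert track.tag_depth["chr1"][1] == 1   # 5' tag at 1,000
        assert track.tag_depth["chr1"][10] == 1  # 3' tag at 10,975
        assert track.tag_depth["chr1"][5] == 0


class TestSegmentContigs:
    def test_full_coverage_no_clusters_one_contig_per_chromosome(self):
        track = coverage_track(_uniform_coverage(), {"chr1": 100_000}, bin_size=1_000)
        contigs = segment_contigs([], track, {"chr1": 100_000})
        assert [(c.chrom, c.start, c.end) for c in contigs] == [("chr1", 0, 100_000)]

    def test_deletion_cluster_cuts_three_contigs(self):
        track = coverage_track(_uniform_coverage(), {"chr1": 100_000}, bin_size=1_000)
        cluster = cluster_for_fusion(("chr1", 40_000, "+"), ("chr1", 60_000, "+"))
        contigs = segment_contigs([cluster], track, {"chr1": 100_000})
        boundaries = sorted({c.start for c in contigs} | {c.end for c in contigs})
        assert boundaries == [0, 40_000, 60_000, 100_000]
        assert len(contigs) == 3

    def test_zero_coverage_run_adds_boundaries(self):
        spans = [("chr1", s, s + 10_000) for s in range(0, 30_001, 1_000)]
        spans += [("chr1", s, s + 10_000) for s in range(60_000, 90_001, 1_000)]
        track = coverage_track(_cpet_frame(spans), {"chr1": 100_000}, bin_size=1_000)
        contigs = segment_contigs([], track, {"chr1": 100_000})
        boundaries = {c.start for c in contigs} | {c.end for c in contigs}
        assert 40_000 in boundaries and 60_000 in boundaries


def _toy_graph(copy_numbers, ref_edges, dpet_edges):
    contigs = [Contig("chr1", k * 10_000, (k + 1) * 10_000, cn)
               for k, cn in enumerate(copy_numbers)]
    graph = nx.MultiGraph()
    for k, contig in enumerate(contigs):
        graph.add_node(k, contig=contig)
    gg = GenomeGraph(contigs=contigs, graph=graph)
    for u, v in ref_edges:
        graph.add_edge(u, v, kind="reference", support=1)
    for n, (u, v, w) in enumerate(dpet_edges):
        edge = DPETEdge(u=u, v=v, weight=w, cluster_id=f"C{n:03d}",
                        end_u="tail", end_v="head")
        gg.dpet_edges.append(edge)
        graph.add_edge(u, v, kind="dpet", weight=w, cluster_id=edge.cluster_id,
                       end_u="tail", end_v="head")
    return gg


class TestBuildGenomeGraph:
    def _track_and_contigs(self):
        track = coverage_track(_uniform_coverage(), {"chr1": 100_000}, bin_size=1_000)
        cluster = cluster_for_fusion(("chr1", 40_000, "+"), ("chr1", 60_000, "+"),
                                     cid="CL1", members=4)
        contigs = segment_contigs([cluster], track, {"chr1": 100_000})
        return cluster, contigs

    def test_reference_edges_need_straddling_cpets(self):
        cluster, contigs = self._track_and_contigs()
        gg = build_genome_graph(contigs, [cluster], _uniform_coverage())
        ref_pairs = {tuple(sorted((u, v)))
                     for u, v, d in gg.graph.edges(data=True) if d["kind"] == "reference"}
        assert (0, 1) in ref_pairs and (1, 2) in ref_pairs

    def test_no_reference_edge_without_straddling_fragments(self):
        # fragments end exactly at the junction: nothing straddles it
        spans = [("chr1", s, 50_000) for s in range(10_000, 40_000, 1_000)]
        spans += [("chr1", 50_000, e) for e in range(60_000, 90_000, 1_000)]
        frame = _cpet_frame(spans)
        track = coverage_track(frame, {"chr1": 100_000}, bin_size=1_000)
        cluster = cluster_for_fusion(("chr1", 30_000, "+"), ("chr1", 50_000, "+"))
        contigs = segment_contigs([cluster], track, {"chr1": 100_000})
        gg = build_genome_graph(contigs, [cluster], frame)
        junctions = {contigs[min(u, v)].end
                     for u, v, d in gg.graph.edges(data=True) if d["kind"] == "reference"}
        assert 50_000 not in junctions

    def test_dpet_edge_weight_is_cluster_size(self):
        cluster, contigs = self._track_and_contigs()
        big = cluster_for_fusion(("chr1", 40_000, "+"), ("chr1", 60_000, "+"),
                                 cid="BIG", members=692, spacing=10)
        gg = build_genome_graph(contigs, [big], _uniform_coverage())
        assert gg.dpet_edges[0].weight == 692

    def test_breakpoint_outside_contigs_raises(self):
        cluster, contigs = self._track_and_contigs()
        stray = cluster_for_fusion(("chr1", 40_000, "+"), ("chr2", 5_000, "+"), cid="S")
        with pytest.raises(InvariantError):
            build_genome_graph(contigs, [stray], _uniform_coverage())


class TestGrowAmplicons:
    def test_toy_chain_grows_through_amplified_neighbours(self):
        gg = _toy_graph([5.0, 5.0, 5.0], ref_edges=[(0, 1), (1, 2)],
                        dpet_edges=[(0, 2, 10)])
        (amp,) = grow_amplicons(gg)
        assert amp.nodes == (0, 1, 2)
        assert amp.seed_edge.weight == 10

    def test_copy_number_exactly_two_is_not_amplified(self):
        # the strict CN > 2 rule skips the middle contig, leaving a two-contig
        # graph that is then discarded
        gg = _toy_graph([5.0, 2.0, 5.0], ref_edges=[(0, 1), (1, 2)],
                        dpet_edges=[(0, 2, 10)])
        assert grow_amplicons(gg) == []
        relaxed = _toy_graph([5.0, 2.01, 5.0], ref_edges=[(0, 1), (1, 2)],
                             dpet_edges=[(0, 2, 10)])
        (amp,) = grow_amplicons(relaxed)
        assert amp.nodes == (0, 1, 2)

    def test_two_contig_graphs_are_discarded(self):
        gg = _toy_graph([5.0, 1.0, 5.0], ref_edges=[], dpet_edges=[(0, 1, 3)])
        assert grow_amplicons(gg) == []

    def test_seed_contigs_exempt_from_amplification_test(self):
        gg = _toy_graph([1.0, 1.0, 5.0], ref_edges=[(1, 2)], dpet_edges=[(0, 1, 7)])
        (amp,) = grow_amplicons(gg)
        assert amp.nodes == (0, 1, 2)

    def test_every_dpet_edge_used_at_most_once(self):
        rng = np.random.default_rng(3)
        cns, refs, dpets = oracles.random_genome_graph(rng)
        gg = _toy_graph(cns, refs, dpets)
        amplicons = grow_amplicons(gg)
        seen = []
        for amp in amplicons:
            seen.extend(e.cluster_id for e in amp.dpet_edges)
        assert len(seen) == len(set(seen))
        all_ids = {e.cluster_id for e in gg.dpet_edges}
        assert set(seen) <= all_ids

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_fixpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cns, refs, dpets = oracles.random_genome_graph(rng)
        # align tie-breaking: feed edges in the implementation's coordinate
        # order so the oracle's input-index tie-break coincides
        dpets = sorted(dpets, key=lambda e: (-e[2], e[0], e[1]))
        gg = _toy_graph(cns, refs, dpets)
        got = [{"seed": amp.seed_edge.cluster_id,
                "nodes": frozenset(amp.nodes),
                "edges": frozenset(e.cluster_id for e in amp.dpet_edges)}
               for amp in grow_amplicons(gg)]
        expected = [
            {"seed": f"C{r['seed']:03d}", "nodes": r["nodes"],
             "edges": frozenset(f"C{k:03d}" for k in r["edges"])}
            for r in oracles.grow_amplicons_oracle(cns, refs, dpets)
        ]
        assert got == expected
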