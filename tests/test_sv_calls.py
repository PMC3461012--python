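"""SV typing from cluster mapping patterns, incl. the insertion taxonomy."""

import numpy as np
import pytest

from conftest import cluster_for_fusion, make_cluster
from petsv.amplicon import CoverageTrack
from petsv.errors import InputError
from petsv.pet_io import LibraryConfig
from petsv.sv_calls import (
    BALANCED_TRANSLOCATION,
    DELETION,
    INSERTION,
    INVERSION,
    ISOLATED_TRANSLOCATION,
    TANDEM_DUPLICATION,
    UNPAIRED_INVERSION,
    SVCall,
    call_single_cluster,
    enumerate_insertion_subtypes,
    match_pair,
    pair_and_call,
    sv_span,
)

CHROM = "chr1"
S1, S2 = 50_000, 54_000          # canonical source segment
T_FWD, T_BWD = 300_000, 10_000   # canonical forward / backward targets


def toy_insertion_clusters(subtype, members=3):
    """Two clusters with the canonical geometry of one insertion sub-type."""
    base = {5: 1, 6: 3}.get(subtype, subtype)
    if base in (1, 2):  # direct intra
        t = T_FWD if base == 1 else T_BWD
        c1 = cluster_for_fusion((CHROM, t, "+"), (CHROM, S1, "+"), cid="P1", members=members)
        c2 = cluster_for_fusion((CHROM, S2, "+"), (CHROM, t, "+"), cid="P2", members=members)
    elif base in (3, 4):  # inverted intra
        t = T_FWD if base == 3 else T_BWD
        c1 = cluster_for_fusion((CHROM, t, "+"), (CHROM, S2, "-"), cid="P1", members=members)
        c2 = cluster_for_fusion((CHROM, S1, "-"), (CHROM, t, "+"), cid="P2", members=members)
    elif subtype == 7:
        c1 = cluster_for_fusion(("chr2", T_FWD, "+"), (CHROM, S1, "+"), cid="P1", members=members)
        c2 = cluster_for_fusion((CHROM, S2, "+"), ("chr2", T_FWD, "+"), cid="P2", members=members)
    else:  # 8: inverted inter
        c1 = cluster_for_fusion(("chr2", T_FWD, "+"), (CHROM, S2, "-"), cid="P1", members=members)
        c2 = cluster_for_fusion((CHROM, S1, "-"), ("chr2", T_FWD, "+"), cid="P2", members=members)
    return c1, c2


class TestSingleClusterCalls:
    def test_long_span_concordant_pattern_is_deletion(self, config_10kb):
        # breakpoint geometry of a validated deletion: chr10:126,631,456..126,720,709
        cluster = cluster_for_fusion(("chr10", 126_631_456, "+"),
                                     ("chr10", 126_720_709, "+"))
        call = call_single_cluster(cluster, config_10kb)
        assert call.sv_type == DELETION
        assert sv_span(call) == 89_253

    def test_reversed_mapping_order_is_tandem_duplication(self, config_10kb):
        cluster = cluster_for_fusion((CHROM, 60_000, "+"), (CHROM, 20_000, "+"))
        assert call_single_cluster(cluster, config_10kb).sv_type == TANDEM_DUPLICATION

    def test_opposite_strands_is_unpaired_inversion(self, config_10kb):
        cluster = cluster_for_fusion((CHROM, 30_000, "+"), (CHROM, 90_000, "-"))
        assert call_single_cluster(cluster, config_10kb).sv_type == UNPAIRED_INVERSION

    def test_two_chromosomes_is_isolated_translocation(self, config_10kb):
        cluster = cluster_for_fusion(("chr9", 133_000_000, "+"), ("chr22", 21_800_000, "+"))
        assert call_single_cluster(cluster, config_10kb).sv_type == ISOLATED_TRANSLOCATION

    def test_concordant_pattern_rejected(self, config_10kb):
        cluster = cluster_for_fusion((CHROM, 100_000, "+"), (CHROM, 105_000, "+"))
        with pytest.raises(InputError):
            call_single_cluster(cluster, config_10kb)

    def test_underspan_pattern_yields_none(self):
        config = LibraryConfig.preset("10kb", concordant_span_min=5_000)
        cluster = cluster_for_fusion((CHROM, 100_000, "+"), (CHROM, 103_000, "+"))
        assert call_single_cluster(cluster, config) is None

    def test_minus_strand_deletion_pattern(self, config_10kb):
        # reverse-strand sampling of the same deletion: both tags on '-'
        cluster = cluster_for_fusion((CHROM, 200_000, "-"), (CHROM, 100_000, "-"))
        assert call_single_cluster(cluster, config_10kb).sv_type == DELETION


class TestInsertionTaxonomy:
    def test_exactly_eight_subtypes(self):
        subtypes = enumerate_insertion_subtypes()
        assert len(subtypes) == 8
        assert [s.number for s in subtypes] == list(range(1, 9))

    def test_intra_inter_partition(self):
        subtypes = enumerate_insertion_subtypes()
        assert all(s.intra_chromosomal for s in subtypes[:6])
        assert all(not s.intra_chromosomal for s in subtypes[6:])
        assert [s.inverted for s in subtypes] == [False, False, True, True,
                                                  False, True, False, True]

    @pytest.mark.parametrize("own", range(1, 9))
    def test_each_predicate_accepts_own_example_and_rejects_others(self, own, config_10kb):
        subtypes = {s.number: s for s in enumerate_insertion_subtypes()}
        c1, c2 = toy_insertion_clusters(own)
        gap = subtypes[own].requires_source_gap
        assert subtypes[own].predicate(c1, c2, config_10kb, source_has_gap=gap)
        for other in range(1, 9):
            if other != own:
                assert not subtypes[other].predicate(c1, c2, config_10kb, source_has_gap=gap)


class TestPairedCalls:
    def test_reciprocal_interchromosomal_pair_is_balanced_translocation(self, config_10kb):
        c1 = cluster_for_fusion(("chr9", 133_000_000, "+"), ("chr22", 21_800_000, "+"), cid="A")
        c2 = cluster_for_fusion(("chr22", 21_800_000, "+"), ("chr9", 133_000_000, "+"), cid="B")
        calls = pair_and_call([c1, c2], config_10kb)
        assert [c.sv_type for c in calls] == [BALANCED_TRANSLOCATION]
        assert set(calls[0].cluster_ids) == {"A", "B"}

    def test_opposite_orientation_pair_is_inversion(self, config_10kb):
        a, b = 100_000, 160_000
        c1 = cluster_for_fusion((CHROM, a, "+"), (CHROM, b, "-"), cid="A")
        c2 = cluster_for_fusion((CHROM, a, "-"), (CHROM, b, "+"), cid="B")
        calls = pair_and_call([c1, c2], config_10kb)
        assert [c.sv_type for c in calls] == [INVERSION]
        assert calls[0].breakpoints == [(CHROM, a), (CHROM, b)]

    def test_lone_cluster_falls_back_to_single_call(self, config_10kb):
        cluster = cluster_for_fusion((CHROM, 100_000, "+"), (CHROM, 200_000, "+"))
        calls = pair_and_call([cluster], config_10kb)
        assert [c.sv_type for c in calls] == [DELETION]

    @pytest.mark.parametrize("subtype", [1, 2, 3, 4, 7, 8])
    def test_copy_insertion_subtypes_called(self, subtype, config_10kb):
        c1, c2 = toy_insertion_clusters(subtype)
        calls = pair_and_call([c1, c2], config_10kb)
        assert len(calls) == 1 and calls[0].sv_type == INSERTION
        assert calls[0].insertion_subtype == subtype
        assert calls[0].source_interval[1:] == (S1, S2)

    @pytest.mark.parametrize("subtype", range(1, 9))
    def test_subtype_invariant_under_cluster_order(self, subtype, config_10kb):
        c1, c2 = toy_insertion_clusters(subtype)
        m1 = match_pair(c1, c2, config_10kb)
        m2 = match_pair(c2, c1, config_10kb)
        base = {5: 1, 6: 3}.get(subtype, subtype)
        assert m1.subtype == m2.subtype == base
        assert m1.source_interval == m2.source_interval

    def _gap_track(self, gap_interval=None):
        bins = np.full(400, 10.0)
        if gap_interval:
            lo, hi = gap_interval
            bins[lo // 1_000:hi // 1_000] = 0.0
        return CoverageTrack(bin_size=1_000, depth={CHROM: bins}, median_depth=10.0,
                             tag_depth={CHROM: bins.copy()}, median_tag_depth=10.0)

    def test_source_coverage_gap_upgrades_to_cut_and_paste(self, config_10kb):
        for subtype, cut_subtype in ((1, 5), (3, 6)):
            c1, c2 = toy_insertion_clusters(subtype)
            track = self._gap_track(gap_interval=(S1, S2))
            calls = pair_and_call([c1, c2], config_10kb, coverage=track)
            assert calls[0].insertion_subtype == cut_subtype
            assert calls[0].caveat is None

    def test_intact_source_coverage_keeps_copy_subtype(self, config_10kb):
        c1, c2 = toy_insertion_clusters(1)
        calls = pair_and_call([c1, c2], config_10kb, coverage=self._gap_track())
        assert calls[0].insertion_subtype == 1 and calls[0].caveat is None

    def test_missing_coverage_flags_caveat(self, config_10kb):
        c1, c2 = toy_insertion_clusters(1)
        calls = pair_and_call([c1, c2], config_10kb, coverage=None)
        assert calls[0].insertion_subtype == 1
        assert calls[0].caveat == "source-coverage-unchecked"

    def test_parsimony_resolves_cut_and_paste_ambiguity(self, config_10kb):
        """A cut-and-paste event admits two equivalent descriptions; the
        smaller moved segment must win even against a higher combined count."""
        s1, s2, t = 50_000, 80_000, 300_000
        j_source = cluster_for_fusion((CHROM, s1, "+"), (CHROM, s2, "+"), cid="J1", members=5)
        j_left = cluster_for_fusion((CHROM, t, "+"), (CHROM, s1, "+"), cid="J2", members=3)
        j_right = cluster_for_fusion((CHROM, s2, "+"), (CHROM, t, "+"), cid="J3", members=3)
        calls = pair_and_call([j_source, j_left, j_right], config_10kb)
        by_type = {c.sv_type: c for c in calls}
        assert set(by_type) == {INSERTION, DELETION}
        assert set(by_type[INSERTION].cluster_ids) == {"J2", "J3"}
        assert by_type[INSERTION].source_interval == (CHROM, s1, s2)
        assert by_type[DELETION].cluster_ids == ("J1",)


class TestSvSpan:
    def test_interchromosomal_undefined(self, config_10kb):
        cluster = cluster_for_fusion(("chr9", 1_000_000, "+"), ("chr22", 2_000_000, "+"))
        call = call_single_cluster(cluster, config_10kb)
        assert sv_span(call) is None

    def test_degenerate_equal_breakpoints(self):
        cluster = cluster_for_fusion((CHROM, 30_000, "+"), (CHROM, 90_000, "-"))
        call = SVCall(UNPAIRED_INVERSION, (cluster,), [(CHROM, 500), (CHROM, 500)])
        assert sv_span(call) == 0
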