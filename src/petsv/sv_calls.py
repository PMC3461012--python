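"""Type dPET clusters as structural variants from their mapping patterns.

Single clusters carry one fusion point: a same-chromosome cluster with the
concordant orientation and order but an over-long span is a deletion; a 3'->5'
mapping order is a tandem duplication; opposite tag strands are an unpaired
inversion; anchors on two chromosomes are an isolated translocation.

Inversions, balanced translocations and insertions are carried by two closely
positioned clusters.  The eight insertion sub-types combine intra- vs
inter-chromosomal source, direct vs inverted orientation, forward vs backward
target position, and (for cut-and-paste events) loss of physical coverage at
the source locus:

    1 intra-chromosomal direct forward      5 deletion + intra direct forward
    2 intra-chromosomal direct backward     6 deletion + intra inverted forward
    3 intra-chromosomal inverted forward    7 inter-chromosomal direct
    4 intra-chromosomal inverted backward   8 inter-chromosomal inverted

Forward/backward has no shared axis between chromosomes, so inter-chromosomal
insertions collapse into sub-types 7 and 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from petsv.clustering import Anchor, DPETCluster
from petsv.errors import InputError
from petsv.pet_io import LibraryConfig

DELETION = "deletion"
TANDEM_DUPLICATION = "tandem_duplication"
UNPAIRED_INVERSION = "unpaired_inversion"
ISOLATED_TRANSLOCATION = "isolated_translocation"
INVERSION = "inversion"
BALANCED_TRANSLOCATION = "balanced_translocation"
INSERTION = "insertion"

SV_TYPES = (
    DELETION, TANDEM_DUPLICATION, UNPAIRED_INVERSION, ISOLATED_TRANSLOCATION,
    INVERSION, BALANCED_TRANSLOCATION, INSERTION,
)

#: anchors on the shared chromosome of a reciprocal cluster pair may be apart
#: by at most this much and still describe one balanced-translocation junction
#: rather than a small inserted segment
RECIPROCAL_MAX_GAP = 1_000
#: anchors of one junction may overlap by at most this much (tag-edge slack)
JUNCTION_OVERLAP_TOL = 50
#: fraction of the genome-wide median physical depth below which a source
#: locus counts as a coverage gap (cut-and-paste evidence)
SOURCE_GAP_DEPTH_FRACTION = 0.05

CAVEAT_SOURCE_UNCHECKED = "source-coverage-unchecked"


@dataclass
class SVCall:
    """One structural variant supported by one or two dPET clusters."""

    sv_type: str
    clusters: tuple[DPETCluster, ...]
    breakpoints: list[tuple[str, int]]
    insertion_subtype: Optional[int] = None
    source_interval: Optional[tuple[str, int, int]] = None
    complexity: str = "unknown"
    supercluster_id: Optional[str] = None
    caveat: Optional[str] = None

    def __post_init__(self) -> None:
        two_cluster = self.sv_type in (INVERSION, BALANCED_TRANSLOCATION, INSERTION)
        if two_cluster != (len(self.clusters) == 2):
            raise InputError(f"{self.sv_type} must have {'two clusters' if two_cluster else 'one cluster'}")
        if (self.insertion_subtype is not None) != (self.sv_type == INSERTION):
            raise InputError("insertion_subtype set iff sv_type is insertion")

    @property
    def cluster_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.clusters)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c.count for c in self.clusters)

    @property
    def count(self) -> int:
        return max(self.counts)

    @property
    def span(self) -> Optional[int]:
        return sv_span(self)


def sv_span(call: SVCall) -> Optional[int]:
    """Distance between outer breakpoints; undefined across chromosomes."""
    chroms = {c for c, _ in call.breakpoints}
    if len(chroms) != 1:
        return None
    positions = [p for _, p in call.breakpoints]
    return max(positions) - min(positions)


# ---------------------------------------------------------------------------
# single-cluster patterns


def _categorize(cluster: DPETCluster, config: LibraryConfig) -> str:
    """Mapping-pattern category of one cluster: del / dup / inv / inter / short."""
    if cluster.chrom5 != cluster.chrom3:
        return "inter"
    s5, s3 = cluster.anchor5.strand, cluster.anchor3.strand
    if s5 != s3:
        return "inv"
    bp5, bp3 = cluster.predicted_bp5, cluster.predicted_bp3
    order_ok = bp5 <= bp3 if s5 == "+" else bp5 >= bp3
    if not order_ok:
        return "dup"
    span = abs(bp3 - bp5)
    if span > config.concordant_span_max:
        return "del"
    if span < config.concordant_span_min:
        return "short"
    raise InputError(
        f"cluster {cluster.id or '?'} matches the concordant pattern "
        f"(same chromosome/strand, correct order, span {span}); not a dPET cluster"
    )


def call_single_cluster(cluster: DPETCluster, config: LibraryConfig) -> Optional[SVCall]:
    """SV call for a lone cluster, or None for an untypeable pattern."""
    category = _categorize(cluster, config)
    breakpoints = [cluster.breakpoint5(), cluster.breakpoint3()]
    if category == "del":
        return SVCall(DELETION, (cluster,), breakpoints)
    if category == "dup":
        return SVCall(TANDEM_DUPLICATION, (cluster,), breakpoints)
    if category == "inv":
        return SVCall(UNPAIRED_INVERSION, (cluster,), breakpoints)
    if category == "inter":
        return SVCall(ISOLATED_TRANSLOCATION, (cluster,), breakpoints)
    return None  # "short": under-span with correct order (novel-sequence insertion; untyped)


# ---------------------------------------------------------------------------
# paired-cluster signature table


@dataclass(frozen=True)
class _AnchorDesc:
    chrom: str
    bp: int
    ext: str  # anchor extends L(eft) or R(ight) of its breakpoint
    start: int
    end: int
    side: str


def _desc(anchor: Anchor, bp: int) -> _AnchorDesc:
    return _AnchorDesc(anchor.chrom, bp, anchor.extends(), anchor.start, anchor.end, anchor.side)


def _descs(cluster: DPETCluster) -> tuple[_AnchorDesc, _AnchorDesc]:
    return (
        _desc(cluster.anchor5, cluster.predicted_bp5),
        _desc(cluster.anchor3, cluster.predicted_bp3),
    )


@dataclass(frozen=True)
class PairMatch:
    """Outcome of matching two clusters against a paired signature."""

    sv_type: str
    subtype: Optional[int]
    breakpoints: tuple[tuple[str, int], ...]
    source_interval: Optional[tuple[str, int, int]]
    shared_distance: int
    source_length: int


def _junction_side(a: _AnchorDesc, b: _AnchorDesc,
                   max_gap: int = RECIPROCAL_MAX_GAP) -> Optional[int]:
    """If two anchors flank one fusion point outward, return its coordinate.

    Requires one Left- and one Right-extending anchor, essentially disjoint
    intervals, and nearly coincident predicted breakpoints.
    """
    if a.ext == b.ext:
        return None
    left, right = (a, b) if a.ext == "L" else (b, a)
    overlap = min(left.end, right.end) - max(left.start, right.start)
    if overlap > JUNCTION_OVERLAP_TOL:
        return None
    if abs(left.bp - right.bp) > max_gap:
        return None
    return (left.bp + right.bp) // 2


def _segment_side(a: _AnchorDesc, b: _AnchorDesc, window: int) -> Optional[tuple[int, int]]:
    """If two anchors delimit an inserted source segment, return (s1, s2).

    The Right-extending anchor starts the segment (breakpoint at its left
    edge), the Left-extending anchor ends it; anchors lie inside the segment,
    so either they overlap (segment shorter than two fragments) or the gap
    between breakpoints clearly exceeds the one-junction tolerance.
    """
    if a.ext == b.ext:
        return None
    first, last = (a, b) if a.ext == "R" else (b, a)
    s1, s2 = first.bp, last.bp
    if s2 <= s1:
        return None
    overlap = min(first.end, last.end) - max(first.start, last.start)
    if overlap <= 0 and (s2 - s1) <= RECIPROCAL_MAX_GAP:
        return None  # indistinguishable from a single junction
    if s2 - s1 > 0 and (overlap > 0 or s2 - s1 > RECIPROCAL_MAX_GAP):
        return (s1, s2)
    return None


def _within(a: int, b: int, window: int) -> bool:
    return abs(a - b) <= window


def _match_intra_direct(c1: DPETCluster, c2: DPETCluster, cat1: str, cat2: str,
                        window: int) -> Optional[PairMatch]:
    """Intra-chromosomal direct insertion: a deletion-like plus a
    duplication-like cluster sharing the target fusion point."""
    if {cat1, cat2} != {"del", "dup"}:
        return None
    d = c1 if cat1 == "del" else c2
    t = c1 if cat1 == "dup" else c2
    d5, d3 = _descs(d)
    t5, t3 = _descs(t)
    chrom = d5.chrom
    # forward: donor reads ... source_end | target ... => del-like 3' anchor
    # and dup-like 5' anchor meet at the target point
    if _within(d3.bp, t5.bp, window):
        s1, s2 = t3.bp, d5.bp
        tgt = (d3.bp + t5.bp) // 2
        if s1 < s2 and tgt > s2:
            return PairMatch(
                INSERTION, 1,
                ((chrom, tgt), (chrom, s1), (chrom, s2)),
                (chrom, s1, s2), abs(d3.bp - t5.bp), s2 - s1,
            )
    # backward: target point upstream of the source segment
    if _within(d5.bp, t3.bp, window):
        s1, s2 = d3.bp, t5.bp
        tgt = (d5.bp + t3.bp) // 2
        if s1 < s2 and tgt < s1:
            return PairMatch(
                INSERTION, 2,
                ((chrom, tgt), (chrom, s1), (chrom, s2)),
                (chrom, s1, s2), abs(d5.bp - t3.bp), s2 - s1,
            )
    return None


def _match_inverted_pair(c1: DPETCluster, c2: DPETCluster, window: int) -> Optional[PairMatch]:
    """Two opposite-orientation intra clusters: inversion, or an intra
    inverted insertion (sub-types 3/4) when they share only the target point."""
    a5, a3 = _descs(c1)
    b5, b3 = _descs(c2)
    chrom = a5.chrom
    strands1 = (c1.anchor5.strand, c1.anchor3.strand)
    strands2 = (c2.anchor5.strand, c2.anchor3.strand)
    if strands1 == strands2:
        return None  # same pattern cannot bracket one segment
    # inversion: the two clusters delimit one segment -- 5' anchors share the
    # left boundary, 3' anchors the right boundary (checked before insertion:
    # the more specific double-junction signature)
    j_left = _junction_side(a5, b5, max_gap=window)
    j_right = _junction_side(a3, b3, max_gap=window)
    if j_left is not None and j_right is not None:
        return PairMatch(
            INVERSION, None,
            ((chrom, min(j_left, j_right)), (chrom, max(j_left, j_right))),
            None, abs(a5.bp - b5.bp) + abs(a3.bp - b3.bp), 0,
        )
    # inverted insertion: one cross-side pair forms the target junction, the
    # remaining anchors delimit the inverted source segment
    for shared, src in (((a5, b3), (b5, a3)), ((b5, a3), (a5, b3))):
        tgt = _junction_side(*shared, max_gap=window)
        if tgt is None:
            continue
        seg = _segment_side(*src, window=window)
        if seg is None:
            continue
        s1, s2 = seg
        if tgt > s2:
            subtype = 3
        elif tgt < s1:
            subtype = 4
        else:
            continue
        return PairMatch(
            INSERTION, subtype,
            ((chrom, tgt), (chrom, s1), (chrom, s2)),
            (chrom, s1, s2), abs(shared[0].bp - shared[1].bp), s2 - s1,
        )
    return None


def _match_inter_pair(c1: DPETCluster, c2: DPETCluster, window: int) -> Optional[PairMatch]:
    """Two reciprocal inter-chromosomal clusters: balanced translocation, or an
    inter-chromosomal insertion (sub-types 7/8)."""
    if not (c1.chrom5 == c2.chrom3 and c1.chrom3 == c2.chrom5):
        return None
    a5, a3 = _descs(c1)
    b5, b3 = _descs(c2)
    # group the four anchors by chromosome: side X pairs c1's 5' with c2's 3'
    side_x = (a5, b3)
    side_y = (a3, b5)
    jx = _junction_side(*side_x)
    jy = _junction_side(*side_y)
    if jx is not None and jy is not None:
        shared = abs(side_x[0].bp - side_x[1].bp) + abs(side_y[0].bp - side_y[1].bp)
        return PairMatch(
            BALANCED_TRANSLOCATION, None,
            ((side_x[0].chrom, jx), (side_y[0].chrom, jy)),
            None, shared, 0,
        )
    for (tgt_pair, src_pair) in ((side_x, side_y), (side_y, side_x)):
        tgt = _junction_side(*tgt_pair, max_gap=window)
        if tgt is None:
            continue
        seg = _segment_side(*src_pair, window=window)
        if seg is None:
            continue
        s1, s2 = seg
        direct = (c1.anchor5.strand == c1.anchor3.strand) and (c2.anchor5.strand == c2.anchor3.strand)
        subtype = 7 if direct else 8
        return PairMatch(
            INSERTION, subtype,
            ((tgt_pair[0].chrom, tgt), (src_pair[0].chrom, s1), (src_pair[0].chrom, s2)),
            (src_pair[0].chrom, s1, s2),
            abs(tgt_pair[0].bp - tgt_pair[1].bp), s2 - s1,
        )
    return None


def match_pair(c1: DPETCluster, c2: DPETCluster, config: LibraryConfig,
               window: int | None = None) -> Optional[PairMatch]:
    """Evaluate the paired-cluster signature table for two clusters.

    Returns the matched signature or None; symmetric in the cluster order.
    """
    if window is None:
        window = config.concordant_span_max
    try:
        cat1 = _categorize(c1, config)
        cat2 = _categorize(c2, config)
    except InputError:
        return None
    intra1 = c1.chrom5 == c1.chrom3
    intra2 = c2.chrom5 == c2.chrom3
    if intra1 and intra2 and c1.chrom5 == c2.chrom5:
        if cat1 == "inv" and cat2 == "inv":
            return _match_inverted_pair(c1, c2, window)
        return _match_intra_direct(c1, c2, cat1, cat2, window)
    if cat1 == "inter" and cat2 == "inter":
        return _match_inter_pair(c1, c2, window)
    return None


# ---------------------------------------------------------------------------
# insertion sub-type taxonomy


@dataclass(frozen=True)
class InsertionSubtype:
    """Descriptor of one insertion sub-type with its signature predicate."""

    number: int
    name: str
    intra_chromosomal: bool
    inverted: bool
    direction: Optional[str]  # forward / backward / None (inter-chromosomal)
    requires_source_gap: bool
    predicate: Callable[..., bool] = field(compare=False)

    def __str__(self) -> str:
        return f"({self.number}) {self.name}"


def _subtype_predicate(number: int, needs_gap: bool):
    base = {5: 1, 6: 3}.get(number, number)

    def predicate(c1: DPETCluster, c2: DPETCluster, config: LibraryConfig,
                  source_has_gap: bool = False) -> bool:
        match = match_pair(c1, c2, config)
        if match is None or match.sv_type != INSERTION or match.subtype != base:
            return False
        return source_has_gap == needs_gap

    return predicate


_SUBTYPE_TABLE = (
    (1, "Intra-chromosomal direct forward insertion", True, False, "forward", False),
    (2, "Intra-chromosomal direct backward insertion", True, False, "backward", False),
    (3, "Intra-chromosomal inverted forward insertion", True, True, "forward", False),
    (4, "Intra-chromosomal inverted backward insertion", True, True, "backward", False),
    (5, "Deletion plus intra-chromosomal direct forward insertion", True, False, "forward", True),
    (6, "Deletion plus intra-chromosomal inverted forward insertion", True, True, "forward", True),
    (7, "Inter-chromosomal direct insertion", False, False, None, False),
    (8, "Inter-chromosomal inverted insertion", False, True, None, False),
)


def enumerate_insertion_subtypes() -> list[InsertionSubtype]:
    """The eight insertion sub-type signatures, in canonical order."""
    return [
        InsertionSubtype(num, name, intra, inv, direction, gap,
                         _subtype_predicate(num, gap))
        for num, name, intra, inv, direction, gap in _SUBTYPE_TABLE
    ]


# ---------------------------------------------------------------------------
# pairing and calling


def _source_has_gap(coverage, source: tuple[str, int, int]) -> bool:
    # a small excised segment is still spanned concordantly by large fragments,
    # so the loss shows in the concordant-tag track, not the fragment footprint
    chrom, start, end = source
    depth = coverage.mean_tag_depth(chrom, start, end)
    return depth <= SOURCE_GAP_DEPTH_FRACTION * coverage.median_tag_depth


def _apply_source_gap(match: PairMatch, coverage) -> tuple[Optional[int], Optional[str]]:
    """Upgrade forward insertions to cut-and-paste sub-types on a coverage gap."""
    subtype = match.subtype
    caveat = None
    if subtype in (1, 3):
        if coverage is None:
            caveat = CAVEAT_SOURCE_UNCHECKED
        elif _source_has_gap(coverage, match.source_interval):
            subtype = 5 if subtype == 1 else 6
    return subtype, caveat


def pair_and_call(clusters: Sequence[DPETCluster], config: LibraryConfig,
                  coverage=None, pairing_window: int | None = None) -> list[SVCall]:
    """Greedily pair clusters against the two-cluster signature table.

    Candidate pairings are ranked by ascending source-segment length (zero
    for inversions/balanced translocations), then descending combined count,
    then ascending shared-point distance: when a rearrangement admits two
    equivalent two-cluster descriptions (cut-and-paste events do), the
    parsimonious one -- the smallest moved segment -- wins.  Unpaired clusters
    fall back to single-cluster calls.

    ``coverage`` is an optional :class:`petsv.amplicon.CoverageTrack`; without
    it, cut-and-paste sub-types 5/6 are reported as 1/3 with a caveat flag.
    """
    if pairing_window is None:
        pairing_window = config.concordant_span_max
    candidates = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            match = match_pair(clusters[i], clusters[j], config, pairing_window)
            if match is not None:
                combined = clusters[i].count + clusters[j].count
                candidates.append((match.source_length, -combined,
                                   match.shared_distance,
                                   clusters[i].id, clusters[j].id, i, j, match))
    candidates.sort(key=lambda item: item[:5])
    used: set[int] = set()
    calls: list[SVCall] = []
    for *_, i, j, match in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        subtype, caveat = (match.subtype, None)
        if match.sv_type == INSERTION:
            subtype, caveat = _apply_source_gap(match, coverage)
        calls.append(SVCall(
            match.sv_type,
            (clusters[i], clusters[j]),
            list(match.breakpoints),
            insertion_subtype=subtype,
            source_interval=match.source_interval,
            caveat=caveat,
        ))
    for k, cluster in enumerate(clusters):
        if k in used:
            continue
        call = call_single_cluster(cluster, config)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: (c.breakpoints[0][0], c.breakpoints[0][1], c.sv_type))
    return calls


# ---------------------------------------------------------------------------
# tabular export


def calls_to_frame(calls: Sequence[SVCall]):
    import pandas as pd

    rows = [{
        "sv_type": c.sv_type,
        "insertion_subtype": c.insertion_subtype if c.insertion_subtype is not None else ".",
        "chroms": ",".join(sorted({ch for ch, _ in c.breakpoints})),
        "breakpoints": ";".join(f"{ch}:{pos}" for ch, pos in c.breakpoints),
        "span": c.span if c.span is not None else ".",
        "counts": ",".join(str(n) for n in c.counts),
        "complexity": c.complexity,
        "supercluster_id": c.supercluster_id or ".",
        "clusters": ",".join(c.cluster_ids),
        "caveat": c.caveat or ".",
    } for c in calls]
    columns = ["sv_type", "insertion_subtype", "chroms", "breakpoints", "span",
               "counts", "complexity", "supercluster_id", "clusters", "caveat"]
    return pd.DataFrame(rows, columns=columns)


def calls_to_vcf(calls: Sequence[SVCall], path) -> None:
    """Minimal VCF export with symbolic SV alleles (translocations as mates)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate">',
        '##INFO=<ID=SUBTYPE,Number=1,Type=Integer,Description="Insertion sub-type 1-8">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=CLUSTERS,Number=.,Type=String,Description="Supporting dPET cluster ids">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    symbolic = {DELETION: "DEL", TANDEM_DUPLICATION: "DUP", INVERSION: "INV",
                UNPAIRED_INVERSION: "INV", INSERTION: "INS"}
    n = 0
    for call in calls:
        n += 1
        ident = f"petsv{n}"
        clusters = ",".join(call.cluster_ids)
        if call.sv_type in symbolic:
            chrom, pos = call.breakpoints[0]
            end = max(p for c, p in call.breakpoints if c == chrom)
            info = f"SVTYPE={symbolic[call.sv_type]};END={end};CLUSTERS={clusters}"
            if call.insertion_subtype is not None:
                info += f";SUBTYPE={call.insertion_subtype}"
            lines.append(f"{chrom}\t{pos + 1}\t{ident}\tN\t<{symbolic[call.sv_type]}>\t.\tPASS\t{info}")
        else:  # translocations: paired breakends
            (c1, p1), (c2, p2) = call.breakpoints[0], call.breakpoints[-1]
            lines.append(f"{c1}\t{p1 + 1}\t{ident}a\tN\tN[{c2}:{p2 + 1}[\t.\tPASS\t"
                         f"SVTYPE=BND;MATEID={ident}b;CLUSTERS={clusters}")
            lines.append(f"{c2}\t{p2 + 1}\t{ident}b\tN\tN]{c1}:{p1 + 1}]\t.\tPASS\t"
                         f"SVTYPE=BND;MATEID={ident}a;CLUSTERS={clusters}")
    with open(path, "wt") as out:
        out.write("\n".join(lines) + "\n")
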