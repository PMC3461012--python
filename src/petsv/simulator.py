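"""Coordinate-level simulator of rearranged genomes and DNA-PET libraries.

The donor (test) genome is an ordered list of reference segments per donor
chromosome, possibly inverted, copied or translocated; planted rearrangements
record their fusion points at base-pair precision.  Fragments are sampled
uniformly along the donor with truncated-normal lengths emulating gel size
selection; the two terminal tags of each fragment are mapped back to reference
coordinates through the segment map.  Masked reference intervals model
unmappable repeats as total tag loss, chimeric ligation joins the ends of two
independent fragments, and PCR duplicates re-emit existing coordinates.

The simulation starts at mapped tags: no nucleotide sequences or mappers are
involved (an optional FASTA emitter exists for integration demos).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from petsv.errors import InputError
from petsv.pet_io import PET_COLUMNS, LibraryConfig, STATUS_UNCLASSIFIED, empty_pet_frame
from petsv import sv_calls as svt


# ---------------------------------------------------------------------------
# donor genome model


@dataclass(frozen=True)
class Segment:
    """One donor segment: a reference interval read forward (+) or inverted (-)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError("segment must satisfy start < end")
        if self.strand not in ("+", "-"):
            raise InputError(f"bad segment strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def entry(self) -> tuple[str, int, str]:
        """Reference coordinate and strand where reading of the segment begins."""
        return (self.chrom, self.start, "+") if self.strand == "+" else (self.chrom, self.end, "-")

    def exit(self) -> tuple[str, int, str]:
        """Reference coordinate and strand where reading of the segment ends."""
        return (self.chrom, self.end, "+") if self.strand == "+" else (self.chrom, self.start, "-")


@dataclass
class DonorChromosome:
    name: str
    segments: list[Segment]
    copies: int = 1

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class FusionPoint:
    """A donor junction joining two non-adjacent reference loci."""

    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str

    def coordinates(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom5, self.pos5), (self.chrom3, self.pos3))


@dataclass(frozen=True)
class ExpectedCall:
    """The SV call a planted event should produce in a perfect analysis."""

    sv_type: str
    subtype: Optional[int]
    breakpoints: tuple[tuple[str, int], ...]
    fusion_points: tuple[FusionPoint, ...]
    primary: bool = True

    @property
    def span(self) -> Optional[int]:
        chroms = {c for c, _ in self.breakpoints}
        if len(chroms) != 1:
            return None
        positions = [p for _, p in self.breakpoints]
        return max(positions) - min(positions)


@dataclass
class TruthEvent:
    event_id: str
    label: str  # e.g. "deletion", "insertion_5"
    expected_calls: tuple[ExpectedCall, ...]

    @property
    def primary(self) -> ExpectedCall:
        return self.expected_calls[0]

    @property
    def fusion_points(self) -> tuple[FusionPoint, ...]:
        return tuple(fp for ec in self.expected_calls for fp in ec.fusion_points)


@dataclass
class GroundTruth:
    """Planted rearrangements with fusion points and expected calls."""

    events: list[TruthEvent] = field(default_factory=list)

    @property
    def n_fusion_points(self) -> int:
        return sum(len(e.fusion_points) for e in self.events)

    def breakpoint_coordinates(self) -> dict[str, np.ndarray]:
        """All true breakpoint coordinates per chromosome (sorted)."""
        coords: dict[str, list[int]] = {}
        for event in self.events:
            for ecall in event.expected_calls:
                for chrom, pos in ecall.breakpoints:
                    coords.setdefault(chrom, []).append(pos)
            for fp in event.fusion_points:
                coords.setdefault(fp.chrom5, []).append(fp.pos5)
                coords.setdefault(fp.chrom3, []).append(fp.pos3)
        return {c: np.unique(np.asarray(v)) for c, v in coords.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for event in self.events:
            for ecall in event.expected_calls:
                rows.append({
                    "event_id": event.event_id,
                    "label": event.label,
                    "sv_type": ecall.sv_type,
                    "subtype": ecall.subtype if ecall.subtype is not None else ".",
                    "primary": ecall.primary,
                    "breakpoints": ";".join(f"{c}:{p}" for c, p in ecall.breakpoints),
                })
        return pd.DataFrame(rows, columns=["event_id", "label", "sv_type", "subtype",
                                           "primary", "breakpoints"])


# ---------------------------------------------------------------------------
# SV requests


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class TandemDuplication:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class UnpairedInversion:
    """Terminal inversion: only one of the two junctions exists, producing a
    single opposite-orientation cluster (the unpaired-inversion signal)."""

    chrom: str
    position: int


@dataclass(frozen=True)
class IsolatedTranslocation:
    """Non-reciprocal: derivative A = A[:a] + B[b:]; the tail of A is lost."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass(frozen=True)
class BalancedTranslocation:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass(frozen=True)
class Insertion:
    """Insertion of a source segment at a target point (sub-types 1-8).

    Sub-types 1-4 copy the source; 5-6 excise it (cut-and-paste, leaving a
    concordant-tag coverage gap); 3/4/6/8 insert it inverted; forward (1/3/5/6)
    means the target lies downstream of the source, backward (2/4) upstream.
    7-8 are inter-chromosomal.
    """

    subtype: int
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_pos: int

    def __post_init__(self) -> None:
        if self.subtype not in range(1, 9):
            raise InputError("insertion subtype must be 1-8")
        intra = self.subtype <= 6
        if intra != (self.source_chrom == self.target_chrom):
            raise InputError(f"subtype {self.subtype} is {'intra' if intra else 'inter'}-chromosomal")
        if self.subtype in (1, 3, 5, 6) and not self.target_pos > self.source_end:
            raise InputError(f"subtype {self.subtype} is a forward insertion (target after source)")
        if self.subtype in (2, 4) and not self.target_pos < self.source_start:
            raise InputError(f"subtype {self.subtype} is a backward insertion (target before source)")

    @property
    def inverted(self) -> bool:
        return self.subtype in (3, 4, 6, 8)

    @property
    def cut(self) -> bool:
        return self.subtype in (5, 6)


SVRequest = (Deletion, TandemDuplication, Inversion, UnpairedInversion,
             IsolatedTranslocation, BalancedTranslocation, Insertion)


# ---------------------------------------------------------------------------
# genome plan


@dataclass
class GenomePlan:
    """Chromosome lengths, masked (unmappable) intervals, planted SVs and the
    resulting donor genome as ordered segment lists."""

    chrom_lengths: dict[str, int]
    masked: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    donor: list[DonorChromosome] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)
    _planted: bool = False

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise InputError(f"chromosome {chrom} has non-positive length")

    def add_mask(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise InputError(f"unknown chromosome {chrom}")
        if not 0 <= start < end <= self.chrom_lengths[chrom]:
            raise InputError("mask outside chromosome")
        self.masked.setdefault(chrom, []).append((start, end))

    def add_donor_chromosome(self, name: str, segments: Sequence[Segment], copies: int = 1) -> None:
        """Append an extra donor chromosome (e.g. an amplicon episome)."""
        for seg in segments:
            if seg.chrom not in self.chrom_lengths:
                raise InputError(f"segment on unknown chromosome {seg.chrom}")
            if seg.end > self.chrom_lengths[seg.chrom]:
                raise InputError("segment beyond chromosome end")
        self.donor.append(DonorChromosome(name, list(segments), copies))

    def ensure_donor(self) -> None:
        """Default to the identity donor when no SVs were planted."""
        if not self._planted:
            plant_svs(self, [])

    def masks_for(self, chrom: str) -> list[tuple[int, int]]:
        return sorted(self.masked.get(chrom, []))

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_json(self) -> dict:
        return {
            "chrom_lengths": dict(self.chrom_lengths),
            "masked": {c: [list(iv) for iv in ivs] for c, ivs in self.masked.items()},
            "donor": [
                {"name": d.name, "copies": d.copies,
                 "segments": [[s.chrom, s.start, s.end, s.strand] for s in d.segments]}
                for d in self.donor
            ],
        }


def donor_junctions(donor_chrom: DonorChromosome) -> list[FusionPoint]:
    """Fusion points of a donor chromosome: consecutive-segment junctions that
    are not reference-adjacent (audit tool; independent of event bookkeeping)."""
    fusions = []
    for prev, nxt in zip(donor_chrom.segments, donor_chrom.segments[1:]):
        c5, p5, s5 = prev.exit()
        c3, p3, s3 = nxt.entry()
        adjacent = (c5 == c3 and s5 == s3 == "+" and p5 == p3)
        adjacent |= (c5 == c3 and s5 == s3 == "-" and p5 == p3)
        if not adjacent:
            fusions.append(FusionPoint(c5, p5, s5, c3, p3, s3))
    return fusions


# ---------------------------------------------------------------------------
# planting


def _reserved_intervals(request) -> list[tuple[str, int, int]]:
    if isinstance(request, (Deletion, TandemDuplication, Inversion)):
        return [(request.chrom, request.start, request.end)]
    if isinstance(request, UnpairedInversion):
        return [(request.chrom, request.position, request.position + 1)]
    if isinstance(request, (IsolatedTranslocation, BalancedTranslocation)):
        return [(request.chrom_a, request.pos_a, request.pos_a + 1),
                (request.chrom_b, request.pos_b, request.pos_b + 1)]
    if isinstance(request, Insertion):
        return [(request.source_chrom, request.source_start, request.source_end),
                (request.target_chrom, request.target_pos, request.target_pos + 1)]
    raise InputError(f"unknown SV request {request!r}")


def _fusion(c5, p5, s5, c3, p3, s3) -> FusionPoint:
    return FusionPoint(c5, int(p5), s5, c3, int(p3), s3)


def _expected(sv_type, breakpoints, fusions, subtype=None, primary=True) -> ExpectedCall:
    return ExpectedCall(sv_type, subtype, tuple(breakpoints), tuple(fusions), primary)


def plant_svs(plan: GenomePlan, requests: Sequence, seed: int = 0) -> GenomePlan:
    """Apply SV requests to the reference and build the donor segment lists.

    Requests must be non-overlapping; every fusion point is recorded at
    base-pair precision together with the calls a perfect analysis would make.
    Extra donor chromosomes added via :meth:`GenomePlan.add_donor_chromosome`
    are preserved.
    """
    del seed  # construction is deterministic; kept for interface symmetry
    extra = [d for d in plan.donor if d.name not in plan.chrom_lengths]
    # validate loci and overlap
    reserved: dict[str, list[tuple[int, int]]] = {}
    for request in requests:
        for chrom, start, end in _reserved_intervals(request):
            if chrom not in plan.chrom_lengths:
                raise InputError(f"request {request} on unknown chromosome {chrom}")
            if not 0 <= start < end <= plan.chrom_lengths[chrom]:
                raise InputError(f"request {request} outside chromosome {chrom}")
            reserved.setdefault(chrom, []).append((start, end))
    for chrom, intervals in reserved.items():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise InputError(f"overlapping SV requests on {chrom} near {s2}")

    truth = GroundTruth()
    serial = [0]

    def new_event(label: str, expected_calls) -> None:
        serial[0] += 1
        truth.events.append(TruthEvent(f"E{serial[0]:03d}", label, tuple(expected_calls)))

    # per-chromosome edit scripts: (position, order, kind, payload)
    ops: dict[str, list[tuple]] = {chrom: [] for chrom in plan.chrom_lengths}
    translocations: list[tuple] = []
    for request in requests:
        if isinstance(request, Deletion):
            ops[request.chrom].append((request.start, "deletion", request))
            chrom, a, b = request.chrom, request.start, request.end
            new_event("deletion", [_expected(
                svt.DELETION, [(chrom, a), (chrom, b)],
                [_fusion(chrom, a, "+", chrom, b, "+")],
            )])
        elif isinstance(request, TandemDuplication):
            ops[request.chrom].append((request.start, "duplication", request))
            chrom, a, b = request.chrom, request.start, request.end
            new_event("tandem_duplication", [_expected(
                svt.TANDEM_DUPLICATION, [(chrom, a), (chrom, b)],
                [_fusion(chrom, b, "+", chrom, a, "+")],
            )])
        elif isinstance(request, Inversion):
            ops[request.chrom].append((request.start, "inversion", request))
            chrom, a, b = request.chrom, request.start, request.end
            new_event("inversion", [_expected(
                svt.INVERSION, [(chrom, a), (chrom, b)],
                [_fusion(chrom, a, "+", chrom, b, "-"),
                 _fusion(chrom, a, "-", chrom, b, "+")],
            )])
        elif isinstance(request, UnpairedInversion):
            chrom, a = request.chrom, request.position
            length = plan.chrom_lengths[chrom]
            ops[chrom].append((a, "terminal_inversion", request))
            new_event("unpaired_inversion", [_expected(
                svt.UNPAIRED_INVERSION, [(chrom, a), (chrom, length)],
                [_fusion(chrom, a, "+", chrom, length, "-")],
            )])
        elif isinstance(request, Insertion):
            src = Segment(request.source_chrom, request.source_start, request.source_end,
                          "-" if request.inverted else "+")
            ops[request.target_chrom].append((request.target_pos, "insert", src))
            if request.cut:
                ops[request.source_chrom].append((request.source_start, "deletion", Deletion(
                    request.source_chrom, request.source_start, request.source_end)))
            t, tc = request.target_pos, request.target_chrom
            s1, s2, sc = request.source_start, request.source_end, request.source_chrom
            f1 = _fusion(tc, t, "+", *src.entry())
            f2 = _fusion(*src.exit(), tc, t, "+")
            expected = [_expected(
                svt.INSERTION, [(tc, t), (sc, s1), (sc, s2)], [f1, f2],
                subtype=request.subtype,
            )]
            if request.cut:
                expected.append(_expected(
                    svt.DELETION, [(sc, s1), (sc, s2)],
                    [_fusion(sc, s1, "+", sc, s2, "+")], primary=False,
                ))
            new_event(f"insertion_{request.subtype}", expected)
        elif isinstance(request, (IsolatedTranslocation, BalancedTranslocation)):
            translocations.append(request)
            a, b = request.pos_a, request.pos_b
            ca, cb = request.chrom_a, request.chrom_b
            if isinstance(request, BalancedTranslocation):
                new_event("balanced_translocation", [_expected(
                    svt.BALANCED_TRANSLOCATION, [(ca, a), (cb, b)],
                    [_fusion(ca, a, "+", cb, b, "+"), _fusion(cb, b, "+", ca, a, "+")],
                )])
            else:
                new_event("isolated_translocation", [_expected(
                    svt.ISOLATED_TRANSLOCATION, [(ca, a), (cb, b)],
                    [_fusion(ca, a, "+", cb, b, "+")],
                )])
        else:
            raise InputError(f"unknown SV request {request!r}")

    # walk each chromosome applying local edits
    donors: dict[str, DonorChromosome] = {}
    for chrom, length in plan.chrom_lengths.items():
        segments: list[Segment] = []
        cur = 0

        def emit(start: int, end: int, strand: str = "+") -> None:
            if end > start:
                segments.append(Segment(chrom, start, end, strand))

        terminal = False
        for pos, kind, payload in sorted(ops[chrom], key=lambda item: item[0]):
            if terminal:
                raise InputError(f"edit after terminal inversion on {chrom}")
            if kind == "deletion":
                emit(cur, payload.start)
                cur = payload.end
            elif kind == "duplication":
                emit(cur, payload.end)
                emit(payload.start, payload.end)
                cur = payload.end
            elif kind == "inversion":
                emit(cur, payload.start)
                emit(payload.start, payload.end, "-")
                cur = payload.end
            elif kind == "terminal_inversion":
                emit(cur, payload.position)
                emit(payload.position, length, "-")
                cur = length
                terminal = True
            elif kind == "insert":
                emit(cur, pos)
                segments.append(payload)
                cur = pos
        emit(cur, length)
        donors[chrom] = DonorChromosome(chrom, segments)

    # arm swaps between finished segment lists
    def split_at(donor: DonorChromosome, chrom: str, pos: int):
        acc = []
        for i, seg in enumerate(donor.segments):
            if seg.chrom == chrom and seg.strand == "+" and seg.start < pos <= seg.end:
                head = donor.segments[:i] + ([Segment(chrom, seg.start, pos)] if pos > seg.start else [])
                tail = ([Segment(chrom, pos, seg.end)] if pos < seg.end else []) + donor.segments[i + 1:]
                return head, tail
            acc.append(seg)
        raise InputError(f"translocation breakpoint {chrom}:{pos} not inside an intact segment")

    for request in translocations:
        da, db = donors[request.chrom_a], donors[request.chrom_b]
        head_a, tail_a = split_at(da, request.chrom_a, request.pos_a)
        head_b, tail_b = split_at(db, request.chrom_b, request.pos_b)
        donors[request.chrom_a] = DonorChromosome(f"der({request.chrom_a})", head_a + tail_b)
        if isinstance(request, BalancedTranslocation):
            donors[request.chrom_b] = DonorChromosome(f"der({request.chrom_b})", head_b + tail_a)
        else:
            donors[request.chrom_b] = DonorChromosome(f"der({request.chrom_b})", head_b)

    plan.donor = [d for d in donors.values() if d.segments] + extra
    plan.truth = truth
    plan._planted = True
    return plan


# ---------------------------------------------------------------------------
# library simulation


_FRAGMENT_PRESETS = {
    "1kb": (1_000.0, 100.0),
    "10kb": (10_000.0, 1_000.0),
    "20kb": (20_000.0, 2_000.0),
}


@dataclass
class SimConfig:
    """Library preset, fragment-length distribution and noise rates."""

    library: LibraryConfig
    fragment_mean: float
    fragment_sd: float
    truncate_sds: float = 4.0
    n_pets: Optional[int] = None
    coverage: Optional[float] = None
    chimera_rate: float = 0.0
    duplicate_rate: float = 0.0
    tag_length: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_mean <= 0:
            raise InputError("fragment_mean must be positive")
        for rate in (self.chimera_rate, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise InputError("rates must be within [0, 1]")
        if (self.n_pets is None) == (self.coverage is None):
            raise InputError("specify exactly one of n_pets / coverage")

    @property
    def fragment_min(self) -> float:
        return max(self.fragment_mean - self.truncate_sds * self.fragment_sd,
                   2 * self.tag_length + 1)

    @property
    def fragment_max(self) -> float:
        return self.fragment_mean + self.truncate_sds * self.fragment_sd

    @classmethod
    def preset(cls, name: str, coverage: Optional[float] = None,
               n_pets: Optional[int] = None, **overrides) -> "SimConfig":
        mean, sd = _FRAGMENT_PRESETS[name]
        kwargs = dict(library=LibraryConfig.preset(name), fragment_mean=mean,
                      fragment_sd=sd, coverage=coverage, n_pets=n_pets)
        kwargs.update(overrides)
        return cls(**kwargs)


def _sample_lengths(config: SimConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    a = (config.fragment_min - config.fragment_mean) / config.fragment_sd
    b = (config.fragment_max - config.fragment_mean) / config.fragment_sd
    lengths = _stats.truncnorm.rvs(a, b, loc=config.fragment_mean,
                                   scale=config.fragment_sd, size=k, random_state=rng)
    return np.maximum(np.rint(lengths).astype(np.int64), 2 * config.tag_length + 1)


def _map_tags(donor: DonorChromosome, positions: np.ndarray, tag: int):
    """Map donor tag start positions to reference coordinates through the
    segment map.  Returns (chrom index, start, end, strand, valid)."""
    seg_len = np.array([s.length for s in donor.segments], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    idx = np.searchsorted(cum, positions, side="right") - 1
    idx = np.clip(idx, 0, len(donor.segments) - 1)
    offset = positions - cum[idx]
    valid = positions + tag <= cum[idx + 1]  # tag must not cross a junction
    seg_start = np.array([s.start for s in donor.segments], dtype=np.int64)[idx]
    seg_end = np.array([s.end for s in donor.segments], dtype=np.int64)[idx]
    fwd = np.array([s.strand == "+" for s in donor.segments])[idx]
    start = np.where(fwd, seg_start + offset, seg_end - offset - tag)
    strand = np.where(fwd, "+", "-")
    return idx, start, start + tag, strand, valid


def _mask_overlaps(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                   plan: GenomePlan) -> np.ndarray:
    hit = np.zeros(len(chroms), dtype=bool)
    for chrom, intervals in plan.masked.items():
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        for mask_start, mask_end in intervals:
            hit |= on_chrom & (starts < mask_end) & (ends > mask_start)
    return hit


def simulate_pets(plan: GenomePlan, config: SimConfig,
                  seed: Optional[int] = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a PET library from the donor genome; returns (PET table, truth).

    Fragment count comes from ``config.n_pets`` or from the requested physical
    coverage of the reference genome.  Reproducible for a fixed seed.
    """
    plan.ensure_donor()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tag = config.tag_length
    n = config.n_pets if config.n_pets is not None else int(
        round(config.coverage * plan.total_length() / config.fragment_mean))
    units = [d for d in plan.donor if d.length > config.fragment_max]
    if not units:
        raise InputError("no donor chromosome long enough for the fragment distribution")
    weights = np.array([d.length * d.copies for d in units], dtype=float)
    counts = rng.multinomial(n, weights / weights.sum())

    chunks = []
    for donor, k in zip(units, counts):
        if k == 0:
            continue
        lengths = _sample_lengths(config, k, rng)
        lengths = np.minimum(lengths, donor.length - 1)
        starts = rng.integers(0, donor.length - lengths + 1)
        seg_chroms = np.array([s.chrom for s in donor.segments], dtype=object)
        i5, s5, e5, st5, ok5 = _map_tags(donor, starts, tag)
        i3, s3, e3, st3, ok3 = _map_tags(donor, starts + lengths - tag, tag)
        keep = ok5 & ok3
        chunks.append(pd.DataFrame({
            "chrom5": seg_chroms[i5[keep]], "start5": s5[keep], "end5": e5[keep],
            "strand5": st5[keep],
            "chrom3": seg_chroms[i3[keep]], "start3": s3[keep], "end3": e3[keep],
            "strand3": st3[keep],
        }))
    if not chunks:
        raise InputError("no PETs were emitted")
    frame = pd.concat(chunks, ignore_index=True)

    # chimeric ligation: the 3' end of one fragment joins the 5' end of another
    n_chimera = int(config.chimera_rate * len(frame))
    if n_chimera >= 2:
        rows = rng.choice(len(frame), size=n_chimera, replace=False)
        perm = rng.permutation(rows)
        cols3 = ["chrom3", "start3", "end3", "strand3"]
        frame.loc[rows, cols3] = frame.loc[perm, cols3].to_numpy()

    # unmappable (masked) reference intervals: total tag loss
    drop = (_mask_overlaps(frame["chrom5"].to_numpy(), frame["start5"].to_numpy(),
                           frame["end5"].to_numpy(), plan)
            | _mask_overlaps(frame["chrom3"].to_numpy(), frame["start3"].to_numpy(),
                             frame["end3"].to_numpy(), plan))
    frame = frame[~drop].reset_index(drop=True)
    if not len(frame):
        raise InputError("all simulated tags fall in masked intervals")

    frame.insert(0, "read_id", [f"P{i:08d}" for i in range(len(frame))])

    # PCR duplicates: re-emit existing coordinates under new read ids
    n_dup = int(config.duplicate_rate * len(frame))
    if n_dup:
        dup_rows = frame.iloc[rng.integers(0, len(frame), size=n_dup)].copy()
        dup_rows["read_id"] = [f"{rid}.dup{k}" for k, rid in enumerate(dup_rows["read_id"])]
        frame = pd.concat([frame, dup_rows], ignore_index=True)

    frame["status"] = STATUS_UNCLASSIFIED
    for col in ("start5", "end5", "start3", "end3"):
        frame[col] = frame[col].astype(np.int64)
    return frame[PET_COLUMNS + ["status"]], plan.truth


def donor_fasta(plan: GenomePlan, reference: Mapping[str, str]) -> Iterable[tuple[str, str]]:
    """Optional donor-sequence emitter for integration demos (untested against
    real mappers): yields (name, sequence) per donor chromosome copy."""
    complement = str.maketrans("ACGTacgt", "TGCAtgca")
    plan.ensure_donor()
    for donor in plan.donor:
        parts = []
        for seg in donor.segments:
            piece = reference[seg.chrom][seg.start:seg.end]
            if seg.strand == "-":
                piece = piece.translate(complement)[::-1]
            parts.append(piece)
        seq = "".join(parts)
        for copy in range(donor.copies):
            suffix = f"_copy{copy + 1}" if donor.copies > 1 else ""
            yield f"{donor.name}{suffix}", seq


# ---------------------------------------------------------------------------
# truth evaluation


def _merged_masks(plan: GenomePlan, chrom: str) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in plan.masks_for(chrom):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def _flank_blocked(plan: GenomePlan, chrom: str, pos: int, tags_left: bool,
                   reach: int) -> bool:
    """True when masks cover the whole flank in which spanning tags must land."""
    lo, hi = (pos - reach, pos) if tags_left else (pos, pos + reach)
    for start, end in _merged_masks(plan, chrom):
        if start <= lo and end >= hi:
            return True
    return False


def _fusion_spannable(fp: FusionPoint, config: SimConfig, plan: GenomePlan) -> bool:
    reach = int(config.fragment_max) - config.tag_length
    side5_left = fp.strand5 == "+"
    side3_left = fp.strand3 == "-"
    if _flank_blocked(plan, fp.chrom5, fp.pos5, side5_left, reach):
        return False
    if _flank_blocked(plan, fp.chrom3, fp.pos3, side3_left, reach):
        return False
    return True


def expected_call_detectable(ecall: ExpectedCall, config: SimConfig, plan: GenomePlan) -> bool:
    """Whether this library could see the expected call at all.

    Deletions need a span clearly beyond the concordant bound once a fragment
    length is added; every fusion point needs at least one unmasked flank
    window on both sides within the maximum fragment length.
    """
    if ecall.sv_type == svt.DELETION:
        span = ecall.span or 0
        threshold = (config.library.concordant_span_max - config.fragment_mean
                     + 2 * config.fragment_sd)
        if span <= threshold:
            return False
    return all(_fusion_spannable(fp, config, plan) for fp in ecall.fusion_points)


@dataclass
class TruthReport:
    """Recall / precision / confusion / resolution of calls against ground truth."""

    recall_by_type: pd.Series
    precision: float
    confusion: pd.DataFrame
    resolution_records: list
    matched_events: dict[str, object]
    undetectable: list[str]
    n_calls: int
    n_matched_calls: int

    @property
    def recall(self) -> float:
        total = int(self.recall_by_type["n"].sum())
        return float(self.recall_by_type["recovered"].sum() / total) if total else float("nan")

    def median_resolution(self) -> float:
        from petsv.compare import median_resolution
        return median_resolution(self.resolution_records)


def _near(pos: int, coords: np.ndarray, tol: int) -> bool:
    if coords.size == 0:
        return False
    i = np.searchsorted(coords, pos)
    best = min(
        abs(pos - coords[i - 1]) if i > 0 else np.inf,
        abs(coords[i] - pos) if i < coords.size else np.inf,
    )
    return best <= tol


def _breakpoints_match(call_bps, expected_bps, tol: int) -> bool:
    for chrom, pos in call_bps:
        if not any(c == chrom and abs(pos - p) <= tol for c, p in expected_bps):
            return False
    for chrom, pos in expected_bps:
        if not any(c == chrom and abs(pos - p) <= tol for c, p in call_bps):
            return False
    return True


def truth_report(ground: GroundTruth, calls: Sequence, config: SimConfig,
                 plan: GenomePlan) -> TruthReport:
    """Score calls against planted rearrangements.

    A call matches a truth fusion point within one nominal insert size.  An
    event is recovered when its primary expected call appears with the right
    type (and insertion sub-type) and matching breakpoints.  Recall is
    conditioned on detectability by the simulated library; precision counts
    calls whose breakpoints all sit near true fusion coordinates.
    """
    from petsv.compare import ResolutionRecord

    tol = config.library.nominal_insert
    truth_coords = ground.breakpoint_coordinates()

    matched_calls = set()
    for k, call in enumerate(calls):
        ok = all(_near(pos, truth_coords.get(chrom, np.array([])), tol)
                 for chrom, pos in call.breakpoints)
        if ok and call.breakpoints:
            matched_calls.add(k)

    matched_events: dict[str, object] = {}
    resolution_records = []
    undetectable = []
    rows = {}
    confusion_rows = []
    for event in ground.events:
        primary = event.primary
        if not expected_call_detectable(primary, config, plan):
            undetectable.append(event.event_id)
            continue
        best = None
        for call in calls:
            if call.sv_type != primary.sv_type:
                continue
            if primary.subtype is not None and call.insertion_subtype != primary.subtype:
                continue
            if _breakpoints_match(call.breakpoints, primary.breakpoints, tol):
                best = call
                break
        label = event.label
        entry = rows.setdefault(label, [0, 0])
        entry[0] += 1
        if best is not None:
            entry[1] += 1
            matched_events[event.event_id] = best
            for side, (chrom, pos) in zip(("left", "right", "third", "fourth"),
                                          best.breakpoints):
                nearest = min((p for c, p in primary.breakpoints if c == chrom),
                              key=lambda p: abs(p - pos), default=None)
                if nearest is not None:
                    resolution_records.append(ResolutionRecord(
                        sv_id=event.event_id, side=side, predicted=pos, truth=nearest))
        # confusion: best type-agnostic breakpoint match
        for call in calls:
            if _breakpoints_match(call.breakpoints, primary.breakpoints, tol):
                confusion_rows.append((label, call.sv_type if call.insertion_subtype is None
                                       else f"insertion_{call.insertion_subtype}"))
                break
        else:
            confusion_rows.append((label, "missed"))

    recall_frame = pd.DataFrame(
        [(label, n, rec, rec / n) for label, (n, rec) in sorted(rows.items())],
        columns=["label", "n", "recovered", "recall"],
    ).set_index("label")
    confusion = pd.crosstab(
        pd.Series([a for a, _ in confusion_rows], name="planted"),
        pd.Series([b for _, b in confusion_rows], name="called"),
    ) if confusion_rows else pd.DataFrame()
    n_calls = len(calls)
    return TruthReport(
        recall_by_type=recall_frame,
        precision=(len(matched_calls) / n_calls) if n_calls else float("nan"),
        confusion=confusion,
        resolution_records=resolution_records,
        matched_events=matched_events,
        undetectable=undetectable,
        n_calls=n_calls,
        n_matched_calls=len(matched_calls),
    )
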