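"""PET data model, table I/O, concordance classification and library statistics.

A PET (paired-end-tag) is the pair of short terminal tags of one size-selected
genomic DNA fragment, each mapped to the reference independently.  Libraries
are carried in memory as pandas DataFrames with one PET per row (columns
``read_id, chrom5, start5, end5, strand5, chrom3, start3, end3, strand3,
status``); :class:`PETRecord` offers a record-level view of single rows.

All coordinates are 0-based half-open.  Genome-browser style tables (1-based
inclusive) can be converted at the I/O boundary with
:func:`to_browser_frame` / :func:`from_browser_frame`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from petsv.errors import InputError

STRANDS = ("+", "-")
STATUS_UNCLASSIFIED = "unclassified"
STATUS_CONCORDANT = "concordant"
STATUS_DISCORDANT = "discordant"

#: canonical column order of the PET table
PET_COLUMNS = [
    "read_id",
    "chrom5", "start5", "end5", "strand5",
    "chrom3", "start3", "end3", "strand3",
]
COORD_COLUMNS = PET_COLUMNS[1:]


@dataclass(frozen=True, slots=True)
class TagAlignment:
    """One mapped tag: a reference interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("tag chromosome name must be non-empty")
        if not self.start < self.end:
            raise InputError(f"tag interval must satisfy start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise InputError(f"unknown strand symbol {self.strand!r}")


@dataclass(frozen=True, slots=True)
class PETRecord:
    """One mapped di-tag: 5' and 3' tag alignments plus concordance status."""

    read_id: str
    tag5: TagAlignment
    tag3: TagAlignment
    status: str = STATUS_UNCLASSIFIED

    @property
    def span(self) -> int | None:
        """Outermost-coordinate distance between the two tags (same chromosome only)."""
        if self.tag5.chrom != self.tag3.chrom:
            return None
        return max(self.tag5.end, self.tag3.end) - min(self.tag5.start, self.tag3.start)

    def to_row(self) -> dict:
        return {
            "read_id": self.read_id,
            "chrom5": self.tag5.chrom, "start5": self.tag5.start,
            "end5": self.tag5.end, "strand5": self.tag5.strand,
            "chrom3": self.tag3.chrom, "start3": self.tag3.start,
            "end3": self.tag3.end, "strand3": self.tag3.strand,
            "status": self.status,
        }

    @classmethod
    def from_row(cls, row) -> "PETRecord":
        return cls(
            read_id=str(row["read_id"]),
            tag5=TagAlignment(row["chrom5"], int(row["start5"]), int(row["end5"]), row["strand5"]),
            tag3=TagAlignment(row["chrom3"], int(row["start3"]), int(row["end3"]), row["strand3"]),
            status=row.get("status", STATUS_UNCLASSIFIED) if hasattr(row, "get") else row["status"],
        )


#: presets: (nominal insert, concordant span max) per library size class
_PRESETS = {
    "1kb": (1_000, 3_000),
    "10kb": (10_000, 20_000),
    "20kb": (20_000, 40_000),
}


@dataclass(frozen=True)
class LibraryConfig:
    """Per-library classification and clustering parameters.

    ``concordant_orientation`` selects the declarative orientation pattern:
    ``"same_strand"`` is the SOLiD mate-pair convention used here by default
    (both tags on the same strand, 5' tag first in reading direction);
    ``"fr"`` covers Illumina forward/reverse paired-end runs.
    ``span_mode`` chooses between outermost-coordinate distance (default) and
    the inner gap between tags when measuring the PET span.
    """

    name: str
    nominal_insert: int
    concordant_span_max: int
    concordant_span_min: int = 0
    concordant_orientation: str = "same_strand"
    span_mode: str = "outer"
    cluster_count_min: int = 3
    specific_cluster_count_min: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.concordant_span_min < self.concordant_span_max):
            raise InputError("need 0 <= concordant_span_min < concordant_span_max")
        if self.cluster_count_min < 1:
            raise InputError("cluster_count_min must be >= 1")
        if self.specific_cluster_count_min < self.cluster_count_min:
            raise InputError("specific_cluster_count_min must be >= cluster_count_min")
        if self.concordant_orientation not in ("same_strand", "fr"):
            raise InputError(f"unknown orientation pattern {self.concordant_orientation!r}")
        if self.span_mode not in ("outer", "inner"):
            raise InputError(f"unknown span mode {self.span_mode!r}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "LibraryConfig":
        """Library presets '1kb' (span max 3 kb), '10kb' (20 kb), '20kb' (40 kb)."""
        try:
            nominal, span_max = _PRESETS[name]
        except KeyError:
            raise InputError(f"unknown library preset {name!r}; choose from {sorted(_PRESETS)}") from None
        kwargs = dict(name=name, nominal_insert=nominal, concordant_span_max=span_max)
        kwargs.update(overrides)
        return cls(**kwargs)


class ParsedTable(NamedTuple):
    """Result of parsing a PET table: the valid rows plus per-line errors."""

    pets: pd.DataFrame
    errors: list[tuple[int, str]]


def empty_pet_frame() -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        PET_COLUMNS + ["status"],
        [str, str, np.int64, np.int64, str, str, np.int64, np.int64, str, str],
    )})
    return frame


def records_to_frame(pets: Iterable[PETRecord]) -> pd.DataFrame:
    rows = [p.to_row() for p in pets]
    if not rows:
        return empty_pet_frame()
    return pd.DataFrame(rows, columns=PET_COLUMNS + ["status"])


def frame_to_records(frame: pd.DataFrame) -> list[PETRecord]:
    return [PETRecord.from_row(row) for row in frame.to_dict("records")]


def as_frame(pets) -> pd.DataFrame:
    """Coerce a PET collection (DataFrame or iterable of PETRecord) to a DataFrame."""
    if isinstance(pets, pd.DataFrame):
        return pets
    return records_to_frame(pets)


# ---------------------------------------------------------------------------
# table I/O


def _parse_line(fields: Sequence[str], bedpe: bool) -> dict:
    if bedpe:
        # BEDPE column order: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2
        if len(fields) < 10:
            raise ValueError(f"expected >=10 BEDPE columns, got {len(fields)}")
        read_id = fields[6]
        c5, s5, e5, st5 = fields[0], fields[1], fields[2], fields[8]
        c3, s3, e3, st3 = fields[3], fields[4], fields[5], fields[9]
    else:
        if len(fields) < 9:
            raise ValueError(f"expected >=9 columns, got {len(fields)}")
        read_id = fields[0]
        c5, s5, e5, st5 = fields[1], fields[2], fields[3], fields[4]
        c3, s3, e3, st3 = fields[5], fields[6], fields[7], fields[8]
    row = {
        "read_id": read_id,
        "chrom5": c5, "start5": int(s5), "end5": int(e5), "strand5": st5,
        "chrom3": c3, "start3": int(s3), "end3": int(e3), "strand3": st3,
    }
    for side in ("5", "3"):
        if not row[f"chrom{side}"]:
            raise ValueError("empty chromosome name")
        if row[f"start{side}"] >= row[f"end{side}"]:
            raise ValueError(f"start >= end for tag {side}")
        if row[f"strand{side}"] not in STRANDS:
            raise ValueError(f"unknown strand symbol {row[f'strand{side}']!r}")
    return row


def read_pet_table(path, config: LibraryConfig | None = None, bedpe: bool = False) -> ParsedTable:
    """Read a tab-delimited PET table (one PET per line, '#' comments).

    Malformed lines (bad coordinates, unknown strand) are rejected but do not
    abort the parse; they are returned as ``(line_number, message)`` pairs.
    When ``config`` is given, records are classified on the fly.
    """
    rows: list[dict] = []
    errors: list[tuple[int, str]] = []
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        try:
            handle = open(path, "rt")
        except OSError as exc:
            raise InputError(f"cannot read PET table {path!r}: {exc}") from exc
        close = True
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                rows.append(_parse_line(line.split("\t"), bedpe))
            except (ValueError, IndexError) as exc:
                errors.append((lineno, str(exc)))
    finally:
        if close:
            handle.close()
    if rows:
        frame = pd.DataFrame(rows, columns=PET_COLUMNS)
        frame["status"] = STATUS_UNCLASSIFIED
    else:
        frame = empty_pet_frame()
    if config is not None and len(frame):
        frame = classify_library(frame, config)
    return ParsedTable(frame, errors)


def write_pet_table(pets, path, bedpe: bool = False) -> None:
    """Write a PET table; coordinates are 0-based half-open (stated in the header)."""
    frame = as_frame(pets)
    with open(path, "wt") as out:
        out.write("# petsv PET table; coordinates 0-based half-open\n")
        if bedpe:
            out.write("# chrom5\tstart5\tend5\tchrom3\tstart3\tend3\tread_id\tscore\tstrand5\tstrand3\n")
            cols = frame[["chrom5", "start5", "end5", "chrom3", "start3", "end3", "read_id"]].copy()
            cols["score"] = "."
            cols["strand5"] = frame["strand5"]
            cols["strand3"] = frame["strand3"]
            cols.to_csv(out, sep="\t", header=False, index=False)
        else:
            out.write("# " + "\t".join(PET_COLUMNS) + "\n")
            frame[PET_COLUMNS].to_csv(out, sep="\t", header=False, index=False)


def to_browser_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert starts to 1-based inclusive (genome-browser) coordinates."""
    out = frame.copy()
    out["start5"] = out["start5"] + 1
    out["start3"] = out["start3"] + 1
    return out


def from_browser_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert a 1-based inclusive table back to 0-based half-open."""
    out = frame.copy()
    out["start5"] = out["start5"] - 1
    out["start3"] = out["start3"] - 1
    return out


def from_alignments(path, max_records: int | None = None) -> pd.DataFrame:
    """Best-effort import of name-paired mate-pair alignments (SAM/BAM) as PETs.

    Primary mapped pairs only; read1 is taken as the 5' tag.  This is a
    convenience importer, not the primary input path.
    """
    import pysam

    pending: dict[str, object] = {}
    rows: list[dict] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or not aln.is_paired:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            first, second = (aln, mate) if aln.is_read1 else (mate, aln)
            rows.append({
                "read_id": aln.query_name,
                "chrom5": first.reference_name, "start5": first.reference_start,
                "end5": first.reference_end, "strand5": "-" if first.is_reverse else "+",
                "chrom3": second.reference_name, "start3": second.reference_start,
                "end3": second.reference_end, "strand3": "-" if second.is_reverse else "+",
            })
            if max_records is not None and len(rows) >= max_records:
                break
    frame = pd.DataFrame(rows, columns=PET_COLUMNS) if rows else empty_pet_frame()
    frame["status"] = STATUS_UNCLASSIFIED
    return frame


# ---------------------------------------------------------------------------
# concordance classification


def _spans(frame: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "outer":
        hi = np.maximum(frame["end5"].to_numpy(), frame["end3"].to_numpy())
        lo = np.minimum(frame["start5"].to_numpy(), frame["start3"].to_numpy())
        return hi - lo
    # inner gap between the facing tag edges, clipped at zero for overlap
    left_end = np.where(frame["start5"] <= frame["start3"], frame["end5"], frame["end3"])
    right_start = np.maximum(frame["start5"].to_numpy(), frame["start3"].to_numpy())
    return np.maximum(right_start - left_end, 0)


def classify_library(pets, config: LibraryConfig) -> pd.DataFrame:
    """Vectorised concordance classification; returns a copy with ``status`` set.

    A PET is concordant iff both tags map to the same chromosome, the
    orientation matches the configured pattern, the 5'->3' tag order is
    correct, and the span lies within the inclusive concordant span range.
    Everything rejected is discordant.
    """
    frame = as_frame(pets).copy()
    if not len(frame):
        return frame
    same_chrom = (frame["chrom5"] == frame["chrom3"]).to_numpy()
    s5 = frame["strand5"].to_numpy()
    s3 = frame["strand3"].to_numpy()
    start5 = frame["start5"].to_numpy()
    start3 = frame["start3"].to_numpy()
    if config.concordant_orientation == "same_strand":
        orient = s5 == s3
        # reading direction: on + the 5' tag precedes the 3' tag, on - it follows
        order = np.where(s5 == "+", start5 <= start3, start5 >= start3)
    else:  # Illumina FR: 5' tag forward and upstream, 3' tag reverse
        orient = (s5 == "+") & (s3 == "-")
        order = start5 <= start3
    span = _spans(frame, config.span_mode)
    in_range = (span >= config.concordant_span_min) & (span <= config.concordant_span_max)
    concordant = same_chrom & orient & order & in_range
    frame["status"] = np.where(concordant, STATUS_CONCORDANT, STATUS_DISCORDANT)
    return frame


def classify_pet(pet: PETRecord, config: LibraryConfig) -> str:
    """Classify one PET as concordant or discordant (total function)."""
    frame = records_to_frame([pet])
    return classify_library(frame, config)["status"].iloc[0]


def split_by_status(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the (concordant, discordant) partitions of a classified table."""
    if (frame["status"] == STATUS_UNCLASSIFIED).any():
        raise InputError("library contains unclassified PETs; run classify_library first")
    return (
        frame[frame["status"] == STATUS_CONCORDANT],
        frame[frame["status"] == STATUS_DISCORDANT],
    )


# ---------------------------------------------------------------------------
# deduplication / down-sampling


def deduplicate(pets) -> pd.DataFrame:
    """Remove PCR-duplicate PETs: keep the first PET per exact coordinate tuple.

    The key is the full (chrom, start, end, strand) tuple of both tags;
    read identity is not consulted.
    """
    frame = as_frame(pets)
    return frame.drop_duplicates(subset=COORD_COLUMNS, keep="first").reset_index(drop=True)


def downsample(pets, required: int, seed: int) -> pd.DataFrame:
    """Bernoulli down-sampling to ~``required`` PETs.

    Each PET is retained independently with probability
    p = required / total, so the retained count is Binomial(total, p).
    Reproducible for a fixed seed.
    """
    frame = as_frame(pets)
    total = len(frame)
    if not 0 <= required <= total:
        raise InputError(f"required count {required} outside [0, {total}]")
    if total == 0:
        return frame.copy()
    p = required / total
    rng = np.random.default_rng(seed)
    keep = rng.random(total) < p
    return frame[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# span / coverage statistics


@dataclass(frozen=True)
class SpanStats:
    """Descriptive statistics of concordant PET spans."""

    n: int
    median: float
    mean: float
    sd: float
    histogram: pd.Series  # counts indexed by bin left edge

    def __str__(self) -> str:
        return (f"n={self.n} median={self.median:.0f} bp "
                f"mean={self.mean:.1f} bp sd={self.sd:.1f} bp")


def span_stats(pets, config: LibraryConfig, bin_width: int | None = None) -> SpanStats:
    """Span distribution of the concordant PETs of a classified library."""
    frame = as_frame(pets)
    cpets = frame[frame["status"] == STATUS_CONCORDANT]
    if not len(cpets):
        raise InputError("no concordant PETs; cannot compute span statistics")
    spans = _spans(cpets, config.span_mode)
    if bin_width is None:
        bin_width = max(config.nominal_insert // 20, 1)
    edges = np.arange(0, spans.max() + bin_width + 1, bin_width)
    counts, _ = np.histogram(spans, bins=edges)
    hist = pd.Series(counts, index=edges[:-1], name="count")
    return SpanStats(
        n=len(spans),
        median=float(np.median(spans)),
        mean=float(np.mean(spans)),
        sd=float(np.std(spans)),  # population SD: a single span has SD 0
        histogram=hist,
    )


def physical_coverage(pets, genome_length: int, span_mode: str = "outer") -> float:
    """Fold physical (fragment) coverage: summed concordant spans / genome length."""
    if genome_length <= 0:
        raise InputError("genome_length must be positive")
    frame = as_frame(pets)
    cpets = frame[frame["status"] == STATUS_CONCORDANT]
    if not len(cpets):
        return 0.0
    return float(_spans(cpets, span_mode).sum()) / genome_length
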