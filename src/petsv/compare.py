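"""Cross-library SV matching and breakpoint-resolution statistics.

Libraries of different insert sizes see different SV spectra: small inserts
catch short deletions, large inserts span repeat-flanked breakpoints and give
higher physical coverage.  SVs are matched across libraries by extending the
larger-insert cluster anchors toward the breakpoints by the library's maximum
insert size and asking whether a same-type SV of the other library falls into
both search windows.  Breakpoint resolution is the distance between a
cluster-predicted breakpoint and the true (validated or simulated) breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from petsv.clustering import Anchor, DPETCluster
from petsv.errors import InputError
from petsv.pet_io import LibraryConfig
from petsv.sv_calls import SVCall

#: resolution threshold (bp) separating well-localised from repeat-degraded
#: breakpoints in the contingency analysis
RESOLUTION_THRESHOLD = 1_500


# ---------------------------------------------------------------------------
# resolution records


@dataclass(frozen=True)
class ResolutionRecord:
    """Distance between a predicted and a true breakpoint coordinate."""

    sv_id: str
    side: str  # left / right
    predicted: int
    truth: int

    @property
    def resolution(self) -> int:
        return abs(self.predicted - self.truth)


def resolution(predicted, truth) -> int:
    """Breakpoint resolution in bp; coordinates may carry chromosome names."""
    if isinstance(predicted, tuple):
        chrom_p, predicted = predicted
        chrom_t, truth = truth
        if chrom_p != chrom_t:
            raise InputError(f"resolution undefined across chromosomes ({chrom_p} vs {chrom_t})")
    return abs(int(predicted) - int(truth))


def median_resolution(records: Sequence) -> float:
    """Median resolution over records (ResolutionRecord or plain bp values)."""
    values = [r.resolution if isinstance(r, ResolutionRecord) else int(r) for r in records]
    if not values:
        raise InputError("no resolution records")
    return float(np.median(values))


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 classification of breakpoints by class and resolution threshold."""

    table: pd.DataFrame  # rows: classes; columns: above / at-or-below threshold
    row_percent_above: pd.Series
    p_value: Optional[float]  # Fisher exact, two-sided (two classes only)
    threshold: int


def resolution_contingency(records_by_class: Mapping[str, Sequence],
                           threshold: int = RESOLUTION_THRESHOLD) -> ContingencyResult:
    """Count breakpoints above/below the resolution threshold per class.

    With exactly two classes, the exact two-sided association probability
    (Fisher exact test on the 2x2 table) is attached.
    """
    rows = {}
    for label, records in records_by_class.items():
        values = [r.resolution if isinstance(r, ResolutionRecord) else int(r) for r in records]
        if not values:
            raise InputError(f"resolution class {label!r} is empty")
        above = sum(v > threshold for v in values)
        rows[label] = (above, len(values) - above)
    table = pd.DataFrame(rows, index=[f">{threshold}", f"<={threshold}"]).T
    pct = 100.0 * table.iloc[:, 0] / table.sum(axis=1)
    pct.name = "percent_above"
    p_value = None
    if len(table) == 2:
        _, p_value = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
        p_value = float(p_value)
    return ContingencyResult(table=table, row_percent_above=pct,
                             p_value=p_value, threshold=threshold)


# ---------------------------------------------------------------------------
# cross-library matching


@dataclass
class LibraryComparison:
    """Common and library-specific SV sets of two libraries.

    The isolated SVs of the reference (larger-insert) library split into
    ``common`` (matched in the other library, possibly by a low-confidence
    cluster of size 2), ``ref_specific`` (unmatched, count at or above the
    raised specific-SV cutoff) and ``ref_low_confidence`` (unmatched below
    it); the three buckets partition the reference call set.
    """

    ref_name: str
    other_name: str
    common: list[tuple[SVCall, SVCall]] = field(default_factory=list)
    ref_specific: list[SVCall] = field(default_factory=list)
    ref_low_confidence: list[SVCall] = field(default_factory=list)
    other_specific: list[SVCall] = field(default_factory=list)

    def venn_table(self) -> pd.DataFrame:
        rows = [
            (f"{self.ref_name} & {self.other_name}", len(self.common)),
            (f"{self.ref_name} specific", len(self.ref_specific)),
            (f"{self.ref_name} unmatched low-confidence", len(self.ref_low_confidence)),
            (f"{self.other_name} specific", len(self.other_specific)),
        ]
        return pd.DataFrame(rows, columns=["set", "n_svs"])

    def span_histograms(self, bin_edges: Sequence[int]) -> pd.DataFrame:
        """Per-category SV span histograms (intra-chromosomal calls only)."""
        buckets = {
            "common": [ref for ref, _ in self.common],
            f"{self.ref_name}_specific": self.ref_specific,
            f"{self.other_name}_specific": self.other_specific,
        }
        edges = np.asarray(list(bin_edges))
        out = {}
        for label, calls in buckets.items():
            spans = [c.span for c in calls if c.span is not None]
            counts, _ = np.histogram(spans, bins=edges)
            out[label] = counts
        frame = pd.DataFrame(out, index=edges[:-1])
        frame.index.name = "span_bin_start"
        return frame


def _search_window(anchor: Anchor, extension: int) -> tuple[str, int, int]:
    """Anchor extended one-sided toward its breakpoint by ``extension``."""
    if anchor.extends() == "L":  # breakpoint at the right edge
        return (anchor.chrom, anchor.start, anchor.end + extension)
    return (anchor.chrom, anchor.start - extension, anchor.end)


def _anchor_in_window(anchor: Anchor, window: tuple[str, int, int]) -> bool:
    chrom, start, end = window
    return anchor.chrom == chrom and anchor.start < end and anchor.end > start


def _cluster_match(ref: DPETCluster, other: DPETCluster, extension: int) -> Optional[int]:
    """Match two clusters of one SV across libraries; return summed breakpoint
    distance, or None."""
    if (ref.anchor5.strand, ref.anchor3.strand) != (other.anchor5.strand, other.anchor3.strand):
        return None
    if not _anchor_in_window(other.anchor5, _search_window(ref.anchor5, extension)):
        return None
    if not _anchor_in_window(other.anchor3, _search_window(ref.anchor3, extension)):
        return None
    return (abs(ref.predicted_bp5 - other.predicted_bp5)
            + abs(ref.predicted_bp3 - other.predicted_bp3))


def _call_match(ref: SVCall, other: SVCall, extension: int) -> Optional[int]:
    if ref.sv_type != other.sv_type:
        return None
    best = None
    for cr in ref.clusters:
        for co in other.clusters:
            dist = _cluster_match(cr, co, extension)
            if dist is not None and (best is None or dist < best):
                best = dist
    return best


def match_across_libraries(ref_calls: Sequence[SVCall], other_calls: Sequence[SVCall],
                           ref_config: LibraryConfig, other_config: LibraryConfig) -> LibraryComparison:
    """Match isolated SVs of a larger-insert reference library against another
    library's calls.

    ``other_calls`` may include low-confidence calls from clusters of size 2;
    those take part in matching but are never reported as library-specific.
    Unmatched reference SVs must reach ``ref_config.specific_cluster_count_min``
    (the raised cutoff) to count as reference-specific.
    """
    ref_chroms = {ch for call in ref_calls for ch, _ in call.breakpoints}
    other_chroms = {ch for call in other_calls for ch, _ in call.breakpoints}
    if ref_chroms and other_chroms and not (ref_chroms & other_chroms):
        raise InputError("libraries share no chromosome names; mismatched genomes?")

    ref_iso = [c for c in ref_calls if c.complexity != "complex"]
    other_iso = [c for c in other_calls if c.complexity != "complex"]
    extension = ref_config.concordant_span_max

    candidates = []
    for i, ref in enumerate(ref_iso):
        for j, other in enumerate(other_iso):
            dist = _call_match(ref, other, extension)
            if dist is not None:
                candidates.append((dist, i, j))
    candidates.sort()
    matched_ref: dict[int, int] = {}
    matched_other: set[int] = set()
    for _, i, j in candidates:
        if i in matched_ref or j in matched_other:
            continue
        matched_ref[i] = j
        matched_other.add(j)

    result = LibraryComparison(ref_name=ref_config.name, other_name=other_config.name)
    for i, ref in enumerate(ref_iso):
        if i in matched_ref:
            result.common.append((ref, other_iso[matched_ref[i]]))
        elif ref.count >= ref_config.specific_cluster_count_min:
            result.ref_specific.append(ref)
        else:
            result.ref_low_confidence.append(ref)
    for j, other in enumerate(other_iso):
        if j not in matched_other and other.count >= other_config.cluster_count_min:
            result.other_specific.append(other)
    return result
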