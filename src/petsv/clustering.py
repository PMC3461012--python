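"""Discordant-PET clustering: group dPETs spanning the same fusion point.

Two dPETs co-cluster iff they share the chromosome pair and strand pair and
both their 5' tags and their 3' tags lie within the library's concordant span
bound of each other; clusters are the transitive closure (single linkage) of
that relation.  The genomic hull of the member 5' (3') tags is the 5' (3')
anchor, and the member tag edge nearest the fusion point gives the predicted
breakpoint on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petsv.errors import InputError
from petsv.pet_io import LibraryConfig, as_frame


@dataclass(frozen=True)
class Anchor:
    """Genomic region covered by the 5' or 3' tags of a cluster."""

    chrom: str
    start: int
    end: int
    strand: str
    side: str  # "5" or "3"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError("anchor must satisfy start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def extends(self) -> str:
        """Which direction the anchor extends away from its breakpoint.

        Tags approach the fusion point in reading direction: a + strand 5'
        anchor lies to the Left of its breakpoint, a + strand 3' anchor to the
        Right; minus strands mirror.
        """
        if self.side == "5":
            return "L" if self.strand == "+" else "R"
        return "R" if self.strand == "+" else "L"


@dataclass
class DPETCluster:
    """A set of dPETs spanning one fusion point."""

    id: str
    anchor5: Anchor
    anchor3: Anchor
    members: tuple[str, ...]  # read ids
    predicted_bp5: int = -1
    predicted_bp3: int = -1
    # tag coordinate arrays kept for breakpoint prediction
    starts5: np.ndarray = field(default=None, repr=False)
    ends5: np.ndarray = field(default=None, repr=False)
    starts3: np.ndarray = field(default=None, repr=False)
    ends3: np.ndarray = field(default=None, repr=False)

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def chrom5(self) -> str:
        return self.anchor5.chrom

    @property
    def chrom3(self) -> str:
        return self.anchor3.chrom

    def breakpoint5(self) -> tuple[str, int]:
        return (self.anchor5.chrom, self.predicted_bp5)

    def breakpoint3(self) -> tuple[str, int]:
        return (self.anchor3.chrom, self.predicted_bp3)


def _predict(side: str, strand: str, starts: np.ndarray, ends: np.ndarray) -> int:
    # the fusion lies beyond the innermost tag edge in reading direction:
    # 5' anchor: + -> max end, - -> min start; 3' anchor mirrored.
    inward = (side == "5") == (strand == "+")
    return int(ends.max()) if inward else int(starts.min())


def predict_breakpoints(cluster: DPETCluster) -> tuple[int, int]:
    """Member-tag coordinate nearest the fusion point on each side."""
    bp5 = _predict("5", cluster.anchor5.strand, cluster.starts5, cluster.ends5)
    bp3 = _predict("3", cluster.anchor3.strand, cluster.starts3, cluster.ends3)
    cluster.predicted_bp5 = bp5
    cluster.predicted_bp3 = bp3
    return bp5, bp3


def _union_find_groups(n: int, joins) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in joins:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def cluster_dpets(dpets, config: LibraryConfig, window: int | None = None) -> list[DPETCluster]:
    """Single-linkage clustering of discordant PETs around shared fusion points.

    ``window`` is the pairwise co-clustering distance between tag start
    coordinates on both sides; it defaults to the concordant span bound of the
    library (two PETs over one fusion point can differ by at most the fragment
    size on each side).
    """
    frame = as_frame(dpets)
    if "status" in frame.columns and (frame["status"] == "concordant").any():
        raise InputError("cluster_dpets expects discordant PETs only")
    if window is None:
        window = config.concordant_span_max
    clusters: list[DPETCluster] = []
    if not len(frame):
        return clusters

    for (c5, c3, s5, s3), group in frame.groupby(
        ["chrom5", "chrom3", "strand5", "strand3"], sort=True
    ):
        g = group.sort_values(["start5", "start3"], kind="mergesort")
        start5 = g["start5"].to_numpy()
        end5 = g["end5"].to_numpy()
        start3 = g["start3"].to_numpy()
        end3 = g["end3"].to_numpy()
        ids = g["read_id"].to_numpy()
        n = len(g)

        def joins():
            for i in range(n):
                for j in range(i + 1, n):
                    if start5[j] - start5[i] > window:
                        break
                    if abs(int(start3[j]) - int(start3[i])) <= window:
                        yield i, j

        for idx_group in _union_find_groups(n, joins()):
            idx = np.asarray(idx_group)
            anchor5 = Anchor(c5, int(start5[idx].min()), int(end5[idx].max()), s5, "5")
            anchor3 = Anchor(c3, int(start3[idx].min()), int(end3[idx].max()), s3, "3")
            cluster = DPETCluster(
                id="",
                anchor5=anchor5,
                anchor3=anchor3,
                members=tuple(ids[idx]),
                starts5=start5[idx], ends5=end5[idx],
                starts3=start3[idx], ends3=end3[idx],
            )
            predict_breakpoints(cluster)
            clusters.append(cluster)

    # deterministic ids: sorted by genomic location
    clusters.sort(key=lambda c: (c.chrom5, c.anchor5.start, c.chrom3, c.anchor3.start, c.anchor5.strand, c.anchor3.strand))
    for k, cluster in enumerate(clusters, start=1):
        cluster.id = f"C{k:06d}"
    return clusters


def filter_clusters(clusters, min_count: int) -> list[DPETCluster]:
    """Drop clusters below the count cutoff (singletons/size-2 are noise)."""
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    return [c for c in clusters if c.count >= min_count]


def clusters_to_frame(clusters) -> pd.DataFrame:
    """Tab-delimited-ready cluster table with anchors, counts and breakpoints."""
    rows = [{
        "cluster_id": c.id,
        "chrom5": c.chrom5, "anchor5_start": c.anchor5.start, "anchor5_end": c.anchor5.end,
        "strand5": c.anchor5.strand,
        "chrom3": c.chrom3, "anchor3_start": c.anchor3.start, "anchor3_end": c.anchor3.end,
        "strand3": c.anchor3.strand,
        "count": c.count,
        "predicted_bp5": c.predicted_bp5, "predicted_bp3": c.predicted_bp3,
        "members": ",".join(c.members),
    } for c in clusters]
    columns = ["cluster_id", "chrom5", "anchor5_start", "anchor5_end", "strand5",
               "chrom3", "anchor3_start", "anchor3_end", "strand3",
               "count", "predicted_bp5", "predicted_bp3", "members"]
    return pd.DataFrame(rows, columns=columns)


def clusters_to_bedpe(clusters) -> pd.DataFrame:
    """Two-interval BEDPE export of cluster anchors (score = cluster count)."""
    rows = [{
        "chrom1": c.chrom5, "start1": c.anchor5.start, "end1": c.anchor5.end,
        "chrom2": c.chrom3, "start2": c.anchor3.start, "end2": c.anchor3.end,
        "name": c.id, "score": c.count,
        "strand1": c.anchor5.strand, "strand2": c.anchor3.strand,
    } for c in clusters]
    columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2"]
    return pd.DataFrame(rows, columns=columns)
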