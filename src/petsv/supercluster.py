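"""Breakpoint interconnection network: isolated versus complex SVs.

Each cluster anchor is extended by the library's maximum insert size on both
sides to form search windows; clusters whose windows overlap anywhere on the
same chromosome join one supercluster (a connected component of the window
overlap graph).  SVs whose clusters sit in superclusters of count 1-3 are
isolated events; the rest are complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from petsv.clustering import DPETCluster
from petsv.pet_io import LibraryConfig
from petsv.sv_calls import SVCall

#: supercluster count above which member SVs are classified as complex
ISOLATED_MAX_COUNT = 3


@dataclass(frozen=True)
class Supercluster:
    """A connected component of window-overlapping dPET clusters."""

    id: str
    member_ids: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.member_ids)


def _windows(cluster: DPETCluster, extension: int):
    for anchor in (cluster.anchor5, cluster.anchor3):
        yield (anchor.chrom, anchor.start - extension, anchor.end + extension)


def build_superclusters(clusters: Sequence[DPETCluster], config: LibraryConfig,
                        extension: int | None = None) -> list[Supercluster]:
    """Group clusters whose extended anchor windows overlap (either anchor).

    Overlap is closed-interval: touching windows join (the edges already carry
    one insert size of slack).  Strand is ignored; the network is positional.
    """
    if extension is None:
        extension = config.concordant_span_max
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, cluster in enumerate(clusters):
        for chrom, start, end in _windows(cluster, extension):
            per_chrom.setdefault(chrom, []).append((start, end, idx))
    for intervals in per_chrom.values():
        intervals.sort()
        # sweep: join each window with every earlier window still reaching it
        active: list[tuple[int, int, int]] = []  # (end, start, idx)
        for start, end, idx in intervals:
            active = [item for item in active if item[0] >= start]
            for _, _, other in active:
                if other != idx:
                    graph.add_edge(idx, other)
            active.append((end, start, idx))
    superclusters = []
    components = sorted(
        (sorted(component) for component in nx.connected_components(graph)),
        key=lambda comp: tuple(clusters[i].id for i in comp),
    )
    for k, component in enumerate(components, start=1):
        superclusters.append(Supercluster(
            id=f"S{k:05d}",
            member_ids=tuple(clusters[i].id for i in component),
        ))
    return superclusters


def classify_complexity(calls: Sequence[SVCall], superclusters: Sequence[Supercluster],
                        isolated_max: int = ISOLATED_MAX_COUNT) -> list[SVCall]:
    """Set complexity on each call: isolated iff every supporting cluster's
    supercluster has count <= ``isolated_max`` (default 3), else complex."""
    by_member: dict[str, Supercluster] = {}
    for sc in superclusters:
        for member in sc.member_ids:
            by_member[member] = sc
    for call in calls:
        counts = []
        sc_ids = []
        for cid in call.cluster_ids:
            sc = by_member.get(cid)
            if sc is None:
                raise KeyError(f"cluster {cid} of a call is not assigned to any supercluster")
            counts.append(sc.count)
            sc_ids.append(sc.id)
        call.complexity = "isolated" if max(counts) <= isolated_max else "complex"
        call.supercluster_id = ",".join(sorted(set(sc_ids)))
    return list(calls)


def supercluster_histogram(superclusters: Sequence[Supercluster]):
    """Distribution of supercluster counts (number of superclusters per count)."""
    import pandas as pd

    counts = pd.Series([sc.count for sc in superclusters], dtype=int)
    hist = counts.value_counts().sort_index()
    hist.index.name = "supercluster_count"
    hist.name = "n_superclusters"
    return hist
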