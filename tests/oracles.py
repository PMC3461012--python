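"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-pairs relations, full enumeration,
repeated-scan fixpoints) and shares no code with the package internals.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# dPET clustering: all-pairs relation + transitive closure


def brute_force_clusters(frame: pd.DataFrame, window: int) -> set[frozenset]:
    """Partition of read ids under the transitive closure of pairwise
    co-clustering (same chromosome pair, same strand pair, both tag starts
    within the window)."""
    graph = nx.Graph()
    rows = frame.to_dict("records")
    graph.add_nodes_from(r["read_id"] for r in rows)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if (a["chrom5"], a["chrom3"], a["strand5"], a["strand3"]) != \
               (b["chrom5"], b["chrom3"], b["strand5"], b["strand3"]):
                continue
            if abs(a["start5"] - b["start5"]) <= window and \
               abs(a["start3"] - b["start3"]) <= window:
                graph.add_edge(a["read_id"], b["read_id"])
    return {frozenset(component) for component in nx.connected_components(graph)}


def random_dpet_frame(rng: np.random.Generator, n: int, window: int) -> pd.DataFrame:
    """Random discordant PETs with hotspot structure so that clusters of
    various sizes, chains and singletons all occur."""
    chrom_pairs = [("chr1", "chr1"), ("chr1", "chr2"), ("chr2", "chr2")]
    strand_pairs = [("+", "+"), ("+", "-"), ("-", "+")]
    n_hotspots = max(int(rng.integers(1, 8)), 1)
    hot5 = rng.integers(0, 2_000_000, size=n_hotspots)
    hot3 = rng.integers(0, 2_000_000, size=n_hotspots)
    rows = []
    for k in range(n):
        if rng.random() < 0.8:  # around a hotspot, jitter on the window scale
            h = int(rng.integers(0, n_hotspots))
            s5 = int(hot5[h] + rng.integers(-2 * window, 2 * window))
            s3 = int(hot3[h] + rng.integers(-2 * window, 2 * window))
        else:
            s5 = int(rng.integers(0, 2_000_000))
            s3 = int(rng.integers(0, 2_000_000))
        s5, s3 = abs(s5), abs(s3)
        cp = chrom_pairs[int(rng.integers(0, len(chrom_pairs)))]
        sp = strand_pairs[int(rng.integers(0, len(strand_pairs)))]
        rows.append({
            "read_id": f"r{k}",
            "chrom5": cp[0], "start5": s5, "end5": s5 + 25, "strand5": sp[0],
            "chrom3": cp[1], "start3": s3, "end3": s3 + 25, "strand3": sp[1],
            "status": "discordant",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# superclustering: adjacency matrix + connected components


def brute_force_superclusters(windows_per_cluster: list[list[tuple[str, int, int]]]) -> set[frozenset]:
    """Partition of cluster indices by any-window closed-interval overlap."""
    n = len(windows_per_cluster)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            for c1, s1, e1 in windows_per_cluster[i]:
                for c2, s2, e2 in windows_per_cluster[j]:
                    if c1 == c2 and s1 <= e2 and s2 <= e1:
                        graph.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(graph)}


# ---------------------------------------------------------------------------
# amplicon growth: exhaustive fixpoint by repeated full scans


def grow_amplicons_oracle(copy_numbers: list[float],
                          ref_edges: list[tuple[int, int]],
                          dpet_edges: list[tuple[int, int, int]],
                          amplified_min_cn: float = 2.0,
                          min_contigs: int = 3) -> list[dict]:
    """Reference semantics of fusion-point-guided growth.

    ``dpet_edges``: (u, v, weight), in a fixed input order whose index breaks
    weight ties exactly like the implementation's coordinate sort would --
    callers must pre-sort accordingly.  Returns one dict per emitted graph
    with the seed index, node set and used dpet edge indices.
    """
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(copy_numbers))}
    for u, v in ref_edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    for u, v, _ in dpet_edges:
        neighbors[u].add(v)
        neighbors[v].add(u)

    order = sorted(range(len(dpet_edges)), key=lambda k: (-dpet_edges[k][2], k))
    used = [False] * len(dpet_edges)
    results = []
    for k in order:
        if used[k]:
            continue
        u, v, _ = dpet_edges[k]
        nodes = {u, v}
        changed = True
        while changed:  # repeated full scan until fixpoint
            changed = False
            for node in list(nodes):
                for nb in neighbors[node]:
                    if nb not in nodes and copy_numbers[nb] > amplified_min_cn:
                        nodes.add(nb)
                        changed = True
        members = [i for i, (a, b, _) in enumerate(dpet_edges)
                   if not used[i] and a in nodes and b in nodes]
        for i in members:
            used[i] = True
        if len(nodes) >= min_contigs:
            results.append({"seed": k, "nodes": frozenset(nodes),
                            "edges": frozenset(members)})
    return results


def random_genome_graph(rng: np.random.Generator, max_contigs: int = 10,
                        max_edges: int = 15):
    """Random contig copy numbers plus reference/dpet edge lists."""
    n = int(rng.integers(2, max_contigs + 1))
    copy_numbers = np.round(rng.uniform(0.5, 8.0, size=n), 2).tolist()
    ref_edges = [(i, i + 1) for i in range(n - 1) if rng.random() < 0.6]
    n_dpet = int(rng.integers(1, max_edges + 1))
    dpet_edges = []
    for _ in range(n_dpet):
        u, v = rng.integers(0, n, size=2)
        dpet_edges.append((int(u), int(v), int(rng.integers(1, 100))))
    return copy_numbers, ref_edges, dpet_edges


# ---------------------------------------------------------------------------
# Fisher exact probability: full margin-fixed enumeration, exact integers


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins.

    Uses exact integer arithmetic; p = sum of probabilities of tables no more
    probable than the observed one.
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denominator = comb(n, col1)

    def weight(x: int) -> int:  # numerator of P(table with top-left = x)
        return comb(row1, x) * comb(row2, col1 - x)

    observed = weight(a)
    total = 0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        w = weight(x)
        if w <= observed:
            total += w
    return total / denominator
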