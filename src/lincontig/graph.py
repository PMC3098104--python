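"""The net of significant clone overlaps and its topological diagnostics.

A cluster of clones tiling a contiguous chromosome segment should form a
*linear* net: a thick path in which every true overlap is corroborated by
short parallel paths through neighbouring clones.  This module provides

* construction of the overlap net at a significance cutoff,
* the TENPP filter (Temporal Exclusion of elements Not Proven by Parallel
  Paths): edges without a 2-5-edge bypass, then vertices with a neighbour
  pair that cannot be reconnected without them, are moved to exclusion
  pools (kept for later restoration during merging),
* diametric-path extraction, vertex ranks relative to it, the linearity
  check, and splitting of non-linear clusters at their branching nodes,
* Pajek ``.net`` export for visual inspection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .metrics import OverlapSet

__all__ = [
    "OverlapGraph",
    "build_graph",
    "parallel_path_exists",
    "tenpp",
    "diametric_path",
    "vertex_ranks",
    "linearity_check",
    "split_nonlinear",
    "export_pajek",
]


@dataclass
class OverlapGraph:
    """Undirected net of significant overlaps plus TENPP exclusion pools."""

    nx: nx.Graph = field(default_factory=nx.Graph)
    excluded_vertices: list[tuple[str, str]] = field(default_factory=list)  # (clone, reason)
    excluded_edges: list[tuple[str, str, str]] = field(default_factory=list)  # (c1, c2, reason)

    @property
    def vertices(self) -> list[str]:
        return sorted(self.nx.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.nx.edges]

    def weight(self, c1: str, c2: str) -> float:
        return float(self.nx.edges[c1, c2]["weight"])

    def subgraph(self, vertices: Iterable[str]) -> "OverlapGraph":
        return OverlapGraph(nx=self.nx.subgraph(vertices).copy())

    def copy(self) -> "OverlapGraph":
        return OverlapGraph(
            nx=self.nx.copy(),
            excluded_vertices=list(self.excluded_vertices),
            excluded_edges=list(self.excluded_edges),
        )


def build_graph(
    overlaps: OverlapSet,
    pr0: float | None = None,
    clone_ids: Sequence[str] | None = None,
    metric: str | None = None,
) -> OverlapGraph:
    """Net with one edge per significant pair; isolated clones are kept."""
    g = nx.Graph()
    ids = clone_ids if clone_ids is not None else overlaps.clone_ids
    g.add_nodes_from(ids)
    members = set(ids)
    for c1, c2, w in overlaps.significant_pairs(pr0, metric):
        if c1 in members and c2 in members:
            g.add_edge(c1, c2, weight=w)
    return OverlapGraph(nx=g)


def _bounded_search(
    g: nx.Graph,
    source: str,
    target: str,
    lmin: int,
    lmax: int,
    forbidden_vertex: str | None,
) -> bool:
    """True iff a simple path of lmin..lmax edges joins source and target.

    Depth-first search pruned by BFS distances to the target; the common
    case (a shared neighbour, path length 2) is checked first.
    """
    if lmin <= 2 <= lmax:
        for nbr in g.adj[source]:
            if nbr != forbidden_vertex and nbr != target and g.has_edge(nbr, target):
                return True
    if lmax <= 2:
        return False
    # BFS distances from target, avoiding the forbidden vertex
    dist: dict[str, int] = {target: 0}
    q = deque([target])
    while q:
        v = q.popleft()
        dv = dist[v]
        if dv >= lmax:
            continue
        for nbr in g.adj[v]:
            if nbr != forbidden_vertex and nbr not in dist:
                dist[nbr] = dv + 1
                q.append(nbr)
    if source not in dist or dist[source] > lmax:
        return False
    if lmin <= dist[source] <= lmax and dist[source] >= 2:
        return True
    # need a simple path with length in range; DFS with pruning
    stack: list[tuple[str, int]] = [(source, 0)]
    on_path: set[str] = {source}
    path: list[str] = [source]
    iters: list[Iterable[str]] = [iter(sorted(g.adj[source]))]
    while iters:
        depth = len(path) - 1
        advanced = False
        for nbr in iters[-1]:
            if nbr == forbidden_vertex or nbr in on_path:
                continue
            if nbr == target:
                if lmin <= depth + 1 <= lmax:
                    return True
                continue
            d = dist.get(nbr)
            if d is None or depth + 1 + d > lmax:
                continue
            path.append(nbr)
            on_path.add(nbr)
            iters.append(iter(sorted(g.adj[nbr])))
            advanced = True
            break
        if not advanced:
            iters.pop()
            on_path.discard(path.pop())
    return False


def parallel_path_exists(
    g: OverlapGraph | nx.Graph,
    endpoints: tuple[str, str],
    forbidden_edge: tuple[str, str] | None = None,
    forbidden_vertex: str | None = None,
    lmin: int = 2,
    lmax: int = 5,
) -> bool:
    """Is there a parallel simple path of ``lmin..lmax`` edges between the
    endpoints that avoids the forbidden edge or vertex?"""
    G = g.nx if isinstance(g, OverlapGraph) else g
    u, v = endpoints
    if u not in G or v not in G:
        raise ValueError(f"endpoints {endpoints} not in graph")
    if forbidden_edge is not None:
        fe = tuple(sorted(forbidden_edge))
        if G.has_edge(*fe):
            G = nx.restricted_view(G, [], [fe])
    return _bounded_search(G, u, v, lmin, lmax, forbidden_vertex)


def tenpp(g: OverlapGraph, lmin: int = 2, lmax: int = 5) -> OverlapGraph:
    """One pass of the parallel-path filter (edge phase, then vertex phase).

    Phase 1 tests every edge against the *input* graph and moves edges
    without a parallel bypass to the exclusion pool.  Phase 2 runs on the
    edge-filtered graph: a vertex is excluded when some pair of its
    neighbours has no 2-5-edge path avoiding it.  The pass is deliberately
    not iterated to a fixpoint; the adaptive clustering loop re-applies it
    per round.
    """
    G = g.nx
    bad_edges = [
        (u, v)
        for u, v in G.edges
        if not parallel_path_exists(G, (u, v), forbidden_edge=(u, v), lmin=lmin, lmax=lmax)
    ]
    kept = G.copy()
    kept.remove_edges_from(bad_edges)
    bad_vertices = []
    for c0 in kept.nodes:
        nbrs = sorted(kept.adj[c0])
        ok = True
        for i, c1 in enumerate(nbrs):
            for c2 in nbrs[i + 1 :]:
                if not _bounded_search(kept, c1, c2, lmin, lmax, forbidden_vertex=c0):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            bad_vertices.append(c0)
    out = OverlapGraph(
        nx=kept,
        excluded_vertices=list(g.excluded_vertices),
        excluded_edges=list(g.excluded_edges),
    )
    for u, v in bad_edges:
        out.excluded_edges.append((*sorted((u, v)), "no-parallel-path"))
    for c0 in bad_vertices:
        for nbr in list(out.nx.adj[c0]):
            out.excluded_edges.append((*sorted((c0, nbr)), "incident-to-excluded-vertex"))
        out.excluded_vertices.append((c0, "neighbor-pair-unproven"))
        out.nx.remove_node(c0)
    return out


def _bfs_paths(G: nx.Graph, source: str) -> tuple[dict[str, int], dict[str, str]]:
    """Deterministic BFS (sorted adjacency): distances and predecessors."""
    dist = {source: 0}
    pred: dict[str, str] = {}
    q = deque([source])
    while q:
        v = q.popleft()
        for nbr in sorted(G.adj[v]):
            if nbr not in dist:
                dist[nbr] = dist[v] + 1
                pred[nbr] = v
                q.append(nbr)
    return dist, pred


def diametric_path(g: OverlapGraph | nx.Graph) -> list[str]:
    """The longest among all-pairs shortest paths (a diameter path).

    Ties are broken deterministically by the lexicographically smallest
    endpoint pair.  Raises on disconnected graphs, naming the components.
    """
    G = g.nx if isinstance(g, OverlapGraph) else g
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph has no diametric path")
    if not nx.is_connected(G):
        comps = [sorted(c)[0] for c in nx.connected_components(G)]
        raise ValueError(
            f"graph is disconnected ({len(comps)} components, e.g. anchored at {comps[:5]})"
        )
    best: tuple[int, str, str] | None = None
    best_pred: dict[str, str] = {}
    for src in sorted(G.nodes):
        dist, pred = _bfs_paths(G, src)
        far = max(dist.values())
        tgt = min(v for v, d in dist.items() if d == far)
        cand = (-far, *sorted((src, tgt)))
        if best is None or cand < best:
            best = cand
            best_pred = pred
            best_src, best_tgt = src, tgt
    path = [best_tgt]
    while path[-1] != best_src:
        path.append(best_pred[path[-1]])
    path.reverse()
    if path[0] > path[-1]:
        path.reverse()
    return path


def vertex_ranks(g: OverlapGraph | nx.Graph, path: Sequence[str]) -> dict[str, int]:
    """Rank of each vertex: edge distance to the nearest path vertex."""
    G = g.nx if isinstance(g, OverlapGraph) else g
    missing = [v for v in path if v not in G]
    if missing:
        raise ValueError(f"path vertices not in graph: {missing[:5]}")
    rank = {v: 0 for v in path}
    q = deque(path)
    while q:
        v = q.popleft()
        for nbr in G.adj[v]:
            if nbr not in rank:
                rank[nbr] = rank[v] + 1
                q.append(nbr)
    for v in G.nodes:  # unreachable vertices (disconnected input) get inf-like rank
        rank.setdefault(v, len(rank) + 1)
    return rank


def linearity_check(
    g: OverlapGraph | nx.Graph,
    max_rank: int = 1,
    path: Sequence[str] | None = None,
) -> tuple[bool, list[str]]:
    """Linear iff no vertex sits further than ``max_rank`` from the
    diametric path.  Returns the branching path vertices otherwise.

    A branching vertex is a path vertex adjacent to an offshoot that
    contains rank >= 2 vertices (removing it disconnects the offshoot).
    """
    G = g.nx if isinstance(g, OverlapGraph) else g
    if G.number_of_nodes() <= 2:
        return True, []
    if path is None:
        path = diametric_path(G)
    rank = vertex_ranks(G, path)
    if all(r <= max_rank for r in rank.values()):
        return True, []
    path_set = set(path)
    off = G.subgraph([v for v in G.nodes if v not in path_set])
    branching: set[str] = set()
    for comp in nx.connected_components(off):
        if max(rank[v] for v in comp) <= max_rank:
            continue
        for v in comp:
            for nbr in G.adj[v]:
                if nbr in path_set:
                    branching.add(nbr)
    return False, sorted(branching)


def split_nonlinear(
    g: OverlapGraph,
    max_rank: int = 1,
    max_iter: int = 100,
) -> tuple[list[OverlapGraph], list[str]]:
    """Split clusters into linear components by removing branching nodes.

    Branching-node clones are excluded (recorded), components recomputed,
    and the test repeated until every component passes the linearity check.
    Returns the linear components and the removed clones.
    """
    removed: list[str] = []
    work = g.nx.copy()
    for _ in range(max_iter):
        bad: list[str] = []
        for comp in nx.connected_components(work):
            ok, branching = linearity_check(work.subgraph(comp))
            if not ok:
                bad.extend(branching if branching else [sorted(comp)[0]])
        if not bad:
            break
        removed.extend(bad)
        work.remove_nodes_from(bad)
    parts = [
        OverlapGraph(nx=work.subgraph(comp).copy())
        for comp in sorted(nx.connected_components(work), key=lambda c: sorted(c)[0])
    ]
    out_excl = list(g.excluded_vertices) + [(v, "branching-node") for v in removed]
    for p in parts:
        p.excluded_vertices = list(out_excl)
    return parts, removed


def export_pajek(g: OverlapGraph | nx.Graph, path: str | Path) -> None:
    """Write a standard Pajek ``.net`` file (vertices with labels, weighted
    edges); round-trips through ``networkx.read_pajek``."""
    G = g.nx if isinstance(g, OverlapGraph) else g
    nodes = sorted(G.nodes)
    index = {v: i + 1 for i, v in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for v in nodes:
            fh.write(f'{index[v]} "{v}"\n')
        fh.write("*Edges\n")
        for u, v, data in G.edges(data=True):
            w = data.get("weight", 1.0)
            fh.write(f"{index[u]} {index[v]} {w:.6g}\n")
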