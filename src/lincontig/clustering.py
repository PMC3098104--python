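"""Single-linkage clustering with an adaptively tightening cutoff.

Clustering clones at a significance cutoff is equivalent to taking the
connected components of the net of overlaps significant at that cutoff.
The adaptive scheme starts liberal (default ``Pr_0 = 1e-12``), cleans
large clusters with the parallel-path filter, freezes clusters of
"reasonable size" (6-500 clones by default) so later rounds cannot
dissolve them, and re-clusters the remaining large clusters at a cutoff
tightened by x1e-3 per round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .fingerprints import FingerprintDB, find_buried
from .graph import OverlapGraph, build_graph, tenpp
from .metrics import OverlapSet

__all__ = ["Partition", "Schedule", "single_linkage", "adaptive_cluster"]

#: Clone states in a partition.
CLUSTERED = "CLUSTERED"
SMALL = "SMALL"
SINGLETON = "SINGLETON"
EXCLUDED = "EXCLUDED"
UNRESOLVED = "UNRESOLVED"
BURIED = "BURIED"


@dataclass
class Partition:
    """Assignment of every clone to a cluster id or a special state."""

    assignment: dict[str, str] = field(default_factory=dict)  # clone -> cluster id
    state: dict[str, str] = field(default_factory=dict)  # clone -> state constant
    round_frozen: dict[str, int] = field(default_factory=dict)  # clone -> round index
    rs_bounds: tuple[int, int] = (6, 500)
    history: list[dict] = field(default_factory=list)

    def clusters(self, min_size: int = 1) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for clone, cid in self.assignment.items():
            out.setdefault(cid, []).append(clone)
        return {
            cid: sorted(members)
            for cid, members in out.items()
            if len(members) >= min_size
        }

    def rs_clusters(self) -> dict[str, list[str]]:
        """Clusters within the reasonable-size bounds."""
        lo, hi = self.rs_bounds
        return {
            cid: m for cid, m in self.clusters().items() if lo <= len(m) <= hi
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tcluster_id\tstate\tround_frozen\n")
            for clone in sorted(self.assignment):
                fh.write(
                    f"{clone}\t{self.assignment[clone]}\t"
                    f"{self.state.get(clone, CLUSTERED)}\t"
                    f"{self.round_frozen.get(clone, -1)}\n"
                )

    def write_history(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.history:
                fh.write(json.dumps(entry) + "\n")


@dataclass
class Schedule:
    """Cutoff schedule of the adaptive clustering loop."""

    pr0: float = 1e-12
    step: float = 1e-3  # multiplicative tightening per round
    max_rounds: int = 10
    large_threshold: int = 500
    rs_bounds: tuple[int, int] = (6, 500)

    def __post_init__(self) -> None:
        if not 0 < self.step < 1:
            raise ValueError("stringency step must tighten the cutoff (0 < step < 1)")

    def cutoff(self, round_index: int) -> float:
        return self.pr0 * self.step**round_index


def _component_partition(
    graph: nx.Graph, rs_bounds: tuple[int, int]
) -> Partition:
    part = Partition(rs_bounds=rs_bounds)
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        cid = members[0]
        state = (
            SINGLETON
            if len(members) == 1
            else (CLUSTERED if len(members) >= rs_bounds[0] else SMALL)
        )
        for c in members:
            part.assignment[c] = cid
            part.state[c] = state
    return part


def single_linkage(
    overlaps: OverlapSet,
    cutoff: float,
    clone_ids: Sequence[str] | None = None,
    rs_bounds: tuple[int, int] = (6, 500),
) -> Partition:
    """Clusters = connected components of the net thresholded at ``cutoff``.

    Cluster ids are deterministic (smallest member id).
    """
    g = build_graph(overlaps, pr0=cutoff, clone_ids=clone_ids)
    return _component_partition(g.nx, rs_bounds)


def adaptive_cluster(
    db: FingerprintDB,
    overlaps: OverlapSet,
    schedule: Schedule | None = None,
    detach_buried: bool = False,
    buried_q: float = 0.90,
) -> tuple[Partition, OverlapGraph]:
    """Adaptive-cutoff clustering with per-round TENPP on large clusters.

    Round ``r``: cluster the unfrozen clones at cutoff ``Pr_r``; run the
    parallel-path filter inside clusters exceeding the large threshold;
    recompute components; freeze reasonable-size clusters; tighten the
    cutoff and repeat while large clusters remain.  Returns the final
    partition and a graph object whose pools carry every TENPP exclusion.

    With ``detach_buried`` buried clones are removed before clustering and
    re-attached to their host's cluster afterwards.
    """
    schedule = schedule or Schedule()
    part = Partition(rs_bounds=schedule.rs_bounds)
    pools = OverlapGraph()
    all_ids = sorted(set(overlaps.clone_ids) & set(db.clone_ids))
    buried_pairs: list[tuple[str, str]] = []
    if detach_buried:
        buried_pairs = find_buried(db, q=buried_q, clone_ids=all_ids)
        buried_set = {b for b, _ in buried_pairs}
        active = [c for c in all_ids if c not in buried_set]
    else:
        active = list(all_ids)
    excluded: set[str] = set()
    frozen: dict[str, str] = {}
    lo, hi = schedule.rs_bounds
    for rnd in range(schedule.max_rounds):
        cutoff = schedule.cutoff(rnd)
        pool = [c for c in active if c not in frozen and c not in excluded]
        if not pool:
            break
        g = build_graph(overlaps, pr0=cutoff, clone_ids=pool)
        # the first round filters the whole net (the parallel-path test is
        # a pre-clustering step); later rounds re-filter only clusters
        # exceeding the large threshold
        n_excl_edges = n_excl_vertices = 0
        comps = list(nx.connected_components(g.nx))
        for comp in comps:
            if rnd > 0 and len(comp) <= schedule.large_threshold:
                continue
            if len(comp) < 2:
                continue
            filtered = tenpp(g.subgraph(comp))
            pools.excluded_edges.extend(
                (u, v, f"round{rnd}:{reason}") for u, v, reason in filtered.excluded_edges
            )
            n_excl_edges += len(filtered.excluded_edges)
            for clone, reason in filtered.excluded_vertices:
                pools.excluded_vertices.append((clone, f"round{rnd}:{reason}"))
                excluded.add(clone)
                n_excl_vertices += 1
            # apply the filtering to the round graph
            g.nx.remove_edges_from([(u, v) for u, v, _ in filtered.excluded_edges])
            g.nx.remove_nodes_from([c for c, _ in filtered.excluded_vertices])
        n_frozen = 0
        large_left = 0
        for comp in nx.connected_components(g.nx):
            members = sorted(comp)
            if lo <= len(members) <= hi:
                cid = members[0]
                for c in members:
                    frozen[c] = cid
                    part.round_frozen[c] = rnd
                n_frozen += 1
            elif len(members) > hi:
                large_left += 1
        part.history.append(
            {
                "round": rnd,
                "cutoff": cutoff,
                "clusters_frozen": n_frozen,
                "excluded_edges": n_excl_edges,
                "excluded_vertices": n_excl_vertices,
                "large_clusters_left": large_left,
            }
        )
        if large_left == 0:
            break
    # assemble the final partition: frozen rs-clusters, leftover small
    # clusters/singletons at the last cutoff, TENPP exclusions
    for c, cid in frozen.items():
        part.assignment[c] = cid
        part.state[c] = CLUSTERED
    leftovers = [c for c in active if c not in frozen and c not in excluded]
    if leftovers:
        g = build_graph(overlaps, pr0=schedule.cutoff(max(len(part.history) - 1, 0)), clone_ids=leftovers)
        for comp in nx.connected_components(g.nx):
            members = sorted(comp)
            cid = members[0]
            if len(members) > hi:
                state = UNRESOLVED
            elif len(members) == 1:
                state = SINGLETON
            elif len(members) < lo:
                state = SMALL
            else:  # pragma: no cover - rs-size leftovers are frozen above
                state = CLUSTERED
            for c in members:
                part.assignment[c] = cid
                part.state[c] = state
    for c in excluded:
        part.assignment[c] = c
        part.state[c] = EXCLUDED
    if detach_buried:
        for buried, host in buried_pairs:
            part.assignment[buried] = part.assignment.get(host, buried)
            part.state[buried] = BURIED
    return part, pools
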