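"""Contig elongation/merging, minimal-tiling-path selection, verification.

After ordering, contigs are elongated by re-admitting temporarily excluded
clones and singletons: two contigs merge when their ends are joined by
significant overlaps (directly or through at most two intermediate
clones), provided the merged net stays topologically linear and no marker
zone conflict arises.  Ambiguous elongations (several mutually exclusive
linear continuations) are reported, never auto-resolved.

The minimal tiling path (MTP) of a contig is the diametric path between
its terminal clones on the net of significant overlaps: every adjacent MTP
pair overlaps significantly and no shorter chain of clones spans the
contig.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .fingerprints import FingerprintDB, find_buried
from .graph import OverlapGraph, build_graph, linearity_check
from .metrics import MetricConfig, ModelCache, OverlapSet, compute_overlaps
from .ordering import ContigOrder, detect_gaps, order_clones

__all__ = [
    "MTP",
    "VerificationReport",
    "select_mtp",
    "elongate",
    "verify_contigs",
]


@dataclass
class MTP:
    """Minimal tiling path of one contig."""

    contig_id: str
    clones: list[str]
    adjacent_log10p: list[float]

    def to_row(self) -> str:
        return "\t".join(
            [self.contig_id, ",".join(self.clones)]
            + [f"{p:.3f}" for p in self.adjacent_log10p]
        )


def select_mtp(contig_graph: OverlapGraph | nx.Graph, order: ContigOrder) -> MTP:
    """MTP = shortest chain (in clone count) of significant overlaps
    between the contig's terminal clones; ties broken by maximal summed
    overlap weight."""
    G = contig_graph.nx if isinstance(contig_graph, OverlapGraph) else contig_graph
    start, end = order.order[0], order.order[-1]
    if start not in G or end not in G:
        raise ValueError("terminal clones missing from the contig graph")
    # Dijkstra over the lexicographic cost (hops, -summed weight)
    best: dict[str, tuple[int, float]] = {start: (0, 0.0)}
    pred: dict[str, str] = {}
    heap: list[tuple[int, float, str]] = [(0, 0.0, start)]
    while heap:
        hops, negw, v = heapq.heappop(heap)
        if (hops, negw) > best.get(v, (math.inf, math.inf)):
            continue
        if v == end:
            break
        for nbr in sorted(G.adj[v]):
            w = float(G.edges[v, nbr].get("weight", 1.0))
            cand = (hops + 1, negw - w)
            if cand < best.get(nbr, (math.inf, math.inf)):
                best[nbr] = cand
                pred[nbr] = v
                heapq.heappush(heap, (*cand, nbr))
    if end not in best:
        raise ValueError(
            f"terminal clones {start!r} and {end!r} are disconnected; "
            "the contig should have been split"
        )
    path = [end]
    while path[-1] != start:
        path.append(pred[path[-1]])
    path.reverse()
    logp = [
        -float(G.edges[a, b].get("weight", 0.0)) for a, b in zip(path, path[1:])
    ]
    return MTP(contig_id=order.order[0], clones=path, adjacent_log10p=logp)


# ---------------------------------------------------------------------------
# Elongation / merging


def _end_connections(
    g: nx.Graph,
    end: str,
    free: set[str],
    targets: Mapping[str, str],
    max_intermediates: int = 2,
) -> dict[str, list[list[str]]]:
    """Other-contig ends reachable from ``end`` via <= ``max_intermediates``
    free clones; returns target end -> list of intermediate chains."""
    found: dict[str, list[list[str]]] = {}
    if end not in g:
        return found
    # depth-limited BFS through free clones only
    frontier: list[tuple[str, list[str]]] = [(end, [])]
    seen = {end}
    for _ in range(max_intermediates + 1):
        nxt: list[tuple[str, list[str]]] = []
        for v, chain in frontier:
            for nbr in sorted(g.adj[v]):
                if nbr in targets and nbr != end:
                    found.setdefault(nbr, []).append(chain)
                elif nbr in free and nbr not in seen and len(chain) < max_intermediates:
                    seen.add(nbr)
                    nxt.append((nbr, chain + [nbr]))
        frontier = nxt
    return found


def _components_linear(G: nx.Graph) -> bool:
    """Linearity of every connected component (contigs may carry internal
    gaps that disconnect them at the working cutoff)."""
    return all(
        linearity_check(G.subgraph(comp))[0] for comp in nx.connected_components(G)
    )


@dataclass
class ElongationEvent:
    kind: str  # merged | singletons-added | ambiguous | vetoed-marker-zone | nonlinear
    contigs: list[str]
    detail: str = ""


def elongate(
    contigs: dict[str, ContigOrder],
    overlaps: OverlapSet,
    relaxed_pr0: float,
    free_clones: Iterable[str] = (),
    marker_zones: Mapping[str, str] | None = None,
    order_seed: int = 0,
    max_intermediates: int = 2,
    max_passes: int = 10,
) -> tuple[dict[str, ContigOrder], list[ElongationEvent]]:
    """Merge contigs end-to-end and attach singletons at a relaxed cutoff.

    ``free_clones`` are the re-admitted candidates (previous TENPP
    exclusions, singletons, small-cluster clones).  A merge is accepted
    only when it is unambiguous, keeps the merged net linear, and does not
    join different marker zones; everything else is reported.
    """
    g = build_graph(overlaps, pr0=relaxed_pr0).nx
    contigs = dict(contigs)
    events: list[ElongationEvent] = []
    zones = dict(marker_zones or {})

    def contig_zones(cid: str) -> set[str]:
        return {zones[c] for c in contigs[cid].order if c in zones}

    changed = True
    passes = 0
    while changed and passes < max_passes:
        changed = False
        passes += 1
        assigned = {c for co in contigs.values() for c in co.order}
        free = {c for c in free_clones if c not in assigned} | {
            c for c in g.nodes if c not in assigned and c in set(free_clones)
        }
        ends: dict[str, str] = {}
        for cid, co in contigs.items():
            ends[co.order[0]] = cid
            ends[co.order[-1]] = cid
        end_partners: dict[str, dict[str, tuple[list[str], str]]] = {}
        for end, cid in ends.items():
            conns = _end_connections(g, end, free, ends, max_intermediates)
            partners: dict[str, tuple[list[str], str]] = {}
            for other_end, chains in conns.items():
                ocid = ends[other_end]
                if ocid == cid:
                    continue
                chain = min(chains, key=len)
                if ocid not in partners or len(chain) < len(partners[ocid][0]):
                    partners[ocid] = (chain, other_end)
            end_partners[end] = partners
        # an end offering several mutually exclusive merges is blocked for
        # this pass — from either side
        blocked: set[str] = set()
        for end, partners in end_partners.items():
            if len(partners) > 1:
                blocked.add(end)
                events.append(
                    ElongationEvent(
                        "ambiguous",
                        sorted([ends[end], *partners]),
                        f"end {end} offers {len(partners)} mutually exclusive merges",
                    )
                )
        merged_now: set[str] = set()
        for end in sorted(end_partners):
            if end in blocked:
                continue
            cid = ends[end]
            for ocid, (chain, other_end) in sorted(end_partners[end].items()):
                if other_end in blocked:
                    continue
                if cid in merged_now or ocid in merged_now:
                    continue
                if cid not in contigs or ocid not in contigs:
                    continue
                za, zb = contig_zones(cid), contig_zones(ocid)
                if za and zb and za.isdisjoint(zb):
                    events.append(
                        ElongationEvent(
                            "vetoed-marker-zone", [cid, ocid], f"zones {za} vs {zb}"
                        )
                    )
                    continue
                union = contigs[cid].order + contigs[ocid].order + chain
                sub = g.subgraph(union)
                if not _components_linear(sub):
                    events.append(
                        ElongationEvent("nonlinear", [cid, ocid], "merged net branches")
                    )
                    continue
                new_order = order_clones(
                    union, overlaps, seed=order_seed, pr0=relaxed_pr0
                )
                for old in (contigs[cid], contigs[ocid]):
                    for host, bb in old.attached_buried.items():
                        new_order.attached_buried.setdefault(host, []).extend(bb)
                new_id = min(cid, ocid)
                for dead in (cid, ocid):
                    contigs.pop(dead, None)
                contigs[new_id] = new_order
                merged_now.update({cid, ocid})
                events.append(
                    ElongationEvent("merged", [cid, ocid], f"via {len(chain)} intermediates")
                )
                changed = True
        # singleton attachment at contig ends
        assigned = {c for co in contigs.values() for c in co.order}
        free = {c for c in free_clones if c not in assigned}
        for cid in sorted(contigs):
            co = contigs[cid]
            for end in (co.order[0], co.order[-1]):
                if end not in g:
                    continue
                addable = sorted(n for n in g.adj[end] if n in free)
                if not addable:
                    continue
                union = co.order + addable
                sub = g.subgraph(union)
                if not _components_linear(sub):
                    events.append(
                        ElongationEvent(
                            "ambiguous", [cid], f"adding {addable} at {end} branches"
                        )
                    )
                    continue
                grown = order_clones(union, overlaps, seed=order_seed, pr0=relaxed_pr0)
                grown.attached_buried = {
                    h: list(bb) for h, bb in co.attached_buried.items()
                }
                contigs[cid] = grown
                free -= set(addable)
                events.append(
                    ElongationEvent("singletons-added", [cid], ",".join(addable))
                )
                changed = True
    return contigs, events


# ---------------------------------------------------------------------------
# Verification of external contigs


@dataclass
class ContigDiagnostics:
    contig_id: str
    n_clones: int
    connected: bool
    n_components: int
    linear: bool
    branching: list[str]
    gaps: list[int]
    categories: list[str]
    missing_clones: list[str] = field(default_factory=list)


@dataclass
class VerificationReport:
    contigs: dict[str, ContigDiagnostics] = field(default_factory=dict)

    @property
    def categories_histogram(self) -> dict[str, int]:
        hist: dict[str, int] = {}
        for d in self.contigs.values():
            for c in d.categories:
                hist[c] = hist.get(c, 0) + 1
        return hist

    def to_json(self, path: str | Path) -> None:
        payload = {
            cid: {
                "n_clones": d.n_clones,
                "connected": d.connected,
                "n_components": d.n_components,
                "linear": d.linear,
                "branching": d.branching,
                "gaps": d.gaps,
                "categories": d.categories,
                "missing_clones": d.missing_clones,
            }
            for cid, d in self.contigs.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "contig_id\tn_clones\tconnected\tn_components\tlinear\t"
                "n_gaps\tcategories\n"
            )
            for cid in sorted(self.contigs):
                d = self.contigs[cid]
                fh.write(
                    f"{cid}\t{d.n_clones}\t{int(d.connected)}\t{d.n_components}\t"
                    f"{int(d.linear)}\t{len(d.gaps)}\t{','.join(d.categories) or '-'}\n"
                )


def read_contig_assignment(path: str | Path) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Read a contig TSV (contig_id, clone_id[, position]).

    Returns (membership, orders); orders only for contigs with positions.
    """
    membership: dict[str, list[str]] = {}
    positions: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("contig_id"):
                continue
            parts = line.split("\t")
            membership.setdefault(parts[0], []).append(parts[1])
            if len(parts) > 2:
                positions.setdefault(parts[0], []).append((int(parts[2]), parts[1]))
    orders = {
        cid: [c for _, c in sorted(pos)] for cid, pos in positions.items()
    }
    return membership, orders


def verify_contigs(
    membership: Mapping[str, Sequence[str]],
    db: FingerprintDB,
    cfg: MetricConfig,
    orders: Mapping[str, Sequence[str]] | None = None,
    models: ModelCache | None = None,
    buried_q: float = 0.90,
    order_seed: int = 0,
) -> VerificationReport:
    """Verify externally supplied contigs against recomputed overlaps.

    Per contig: recompute pairwise p-values, test net connectivity and
    topological linearity, locate gaps in the supplied order, and classify
    problems into the categories non-connected, buried-conflict,
    reorder-fixable, marker-conflict and non-linear.
    """
    orders = dict(orders or {})
    if models is None and ("siid" in cfg.metrics or "sind" in cfg.metrics):
        models = ModelCache(cfg, db.ensure_abundances())
    report = VerificationReport()
    for cid in sorted(membership):
        clones = list(membership[cid])
        missing = [c for c in clones if c not in db]
        present = [c for c in clones if c in db]
        if len(present) < 2:
            report.contigs[cid] = ContigDiagnostics(
                cid, len(present), True, 1, True, [], [], [], missing
            )
            continue
        ov = compute_overlaps(db, cfg, clone_ids=present, models=models)
        g = build_graph(ov, pr0=cfg.pr0)
        comps = list(nx.connected_components(g.nx))
        connected = len(comps) == 1
        categories: list[str] = []
        if not connected:
            categories.append("non-connected")
        linear, branching = True, []
        if connected:
            linear, branching = linearity_check(g)
            if not linear:
                categories.append("non-linear")
        gaps: list[int] = []
        supplied = orders.get(cid)
        if supplied:
            gaps = detect_gaps([c for c in supplied if c in db], ov)
            if gaps and connected and linear:
                reordered = order_clones(present, ov, seed=order_seed)
                if not reordered.gaps:
                    categories.append("reorder-fixable")
        # buried-conflict: connectivity lost after detaching buried clones
        if connected:
            buried = [b for b, _ in find_buried(db, q=buried_q, clone_ids=present)]
            rest = [c for c in present if c not in buried]
            if len(rest) >= 2 and not nx.is_connected(g.nx.subgraph(rest)):
                categories.append("buried-conflict")
        # marker-conflict: a marker shared by clones without significant overlap
        marker_holders: dict[str, list[str]] = {}
        for c in present:
            for mk in db[c].markers:
                marker_holders.setdefault(mk, []).append(c)
        conflict = False
        for mk, holders in marker_holders.items():
            for i, a in enumerate(holders):
                for b in holders[i + 1 :]:
                    if not g.nx.has_edge(a, b):
                        conflict = True
        if conflict:
            categories.append("marker-conflict")
        report.contigs[cid] = ContigDiagnostics(
            cid,
            len(present),
            connected,
            len(comps),
            linear,
            branching,
            gaps,
            categories,
            missing,
        )
    return report
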