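"""Global-optimization ordering of clones within a linear cluster.

The order criterion is ``W(O) = sum_adjacent W_ij - b(O) * W0`` where
``W_ij = -log10 Pr(c_i, c_j)``, ``b(O)`` counts adjacent pairs whose
overlap is not significant at ``Pr_0`` and ``W0`` penalises each such gap.
Maximising ``W(O)`` is an open-path Traveling Salesman Problem with
distances ``d(c_i, c_j) = Wmax - W_ij + W0 * 1{Pr > Pr_0}``; it is solved
here with a multi-start nearest-neighbour construction refined by 2-opt
and Or-opt moves (the classic dummy-city trick turns the open path into a
closed tour).

Order robustness is assessed by jackknife resampling of the *band
universe*: each replicate drops a small fraction of the band classes,
recomputes overlaps over the kept bands (against the same calibrated tail
models), reorders, and tallies each clone's left/right neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fingerprints import BandClassKeep, FingerprintDB
from .metrics import MetricConfig, ModelCache, OverlapSet, compute_overlaps

__all__ = [
    "TSPInstance",
    "ContigOrder",
    "StabilityReport",
    "tsp_distances",
    "order_clones",
    "detect_gaps",
    "jackknife",
    "skeleton_order",
]


@dataclass
class TSPInstance:
    """Distance matrix and overlap weights for one cluster."""

    clone_ids: list[str]
    dist: np.ndarray  # d(c_i, c_j), symmetric, zero diagonal
    weight: np.ndarray  # W_ij = -log10 Pr
    significant: np.ndarray  # bool, overlap significant at Pr_0
    w0: float
    w_max: float


@dataclass
class ContigOrder:
    """An ordered cluster with its criterion value and gap positions."""

    order: list[str]
    criterion: float
    gaps: list[int]  # positions i with non-significant overlap (i, i+1)
    w0: float
    attached_buried: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    @property
    def members(self) -> list[str]:
        """All clones of the contig: ordered clones plus attached buried."""
        return list(self.order) + [
            b for host in self.order for b in self.attached_buried.get(host, [])
        ]


@dataclass
class StabilityReport:
    """Jackknife neighbour frequencies and per-clone instability."""

    neighbor_freq: dict[str, dict[str, dict[str, float]]]  # clone -> side -> nbr -> freq
    instability: dict[str, float]
    replicates: int
    band_fraction: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tside\tneighbor\tfrequency\tinstability\n")
            for clone in sorted(self.neighbor_freq):
                for side in ("left", "right"):
                    for nbr, freq in sorted(self.neighbor_freq[clone][side].items()):
                        fh.write(
                            f"{clone}\t{side}\t{nbr}\t{freq:.4f}\t"
                            f"{self.instability[clone]:.4f}\n"
                        )


def tsp_distances(
    cluster: Sequence[str],
    overlaps: OverlapSet,
    pr0: float | None = None,
    w0: float | None = None,
    metric: str | None = None,
) -> TSPInstance:
    """Distance matrix ``d = Wmax - W + W0 * 1{not significant}``.

    Unevaluated (prefiltered) pairs enter with ``W = 0``.  ``W0`` defaults
    to ``-log10 Pr_0`` so that one gap costs one threshold-grade link.
    """
    ids = sorted(cluster)
    n = len(ids)
    if n < 2:
        raise ValueError("cannot order a cluster of fewer than 2 clones")
    pr0 = pr0 if pr0 is not None else overlaps.cfg.pr0
    cut = -math.log10(pr0)
    if w0 is None:
        w0 = cut
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            W[i, j] = W[j, i] = overlaps.weight(ids[i], ids[j], metric)
    w_max = float(W.max())
    sig = W > cut
    dist = w_max - W + w0 * (~sig)
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sig, False)
    return TSPInstance(ids, dist, W, sig, float(w0), w_max)


def _criterion(inst: TSPInstance, perm: np.ndarray) -> tuple[float, list[int]]:
    a, b = perm[:-1], perm[1:]
    total = float(inst.weight[a, b].sum())
    gaps = np.flatnonzero(~inst.significant[a, b]).tolist()
    return total - inst.w0 * len(gaps), gaps


def _nearest_neighbour(dist: np.ndarray, start: int) -> np.ndarray:
    n = dist.shape[0]
    seen = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    order[0] = start
    seen[start] = True
    cur = start
    for i in range(1, n):
        d = np.where(seen, np.inf, dist[cur])
        cur = int(np.argmin(d))
        order[i] = cur
        seen[cur] = True
    return order


def _two_opt(dist: np.ndarray, tour: np.ndarray, max_sweeps: int = 80) -> np.ndarray:
    """First-improvement 2-opt on a closed tour, vectorised per anchor."""
    n = tour.size
    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for i in range(n - 1):
            a, b = tour[i], tour[i + 1]
            # candidate second edges (c, d) at positions j, j+1 with j > i+1
            j = np.arange(i + 2, n)
            c = tour[j]
            d = tour[(j + 1) % n]
            delta = dist[a, c] + dist[b, d] - dist[a, b] - dist[c, d]
            best = int(np.argmin(delta)) if delta.size else -1
            if best >= 0 and delta[best] < -1e-9:
                jj = i + 2 + best
                tour[i + 1 : jj + 1] = tour[i + 1 : jj + 1][::-1]
                improved = True
    return tour


def _or_opt(dist: np.ndarray, tour: np.ndarray, max_sweeps: int = 40) -> np.ndarray:
    """Relocate segments of 1-3 vertices while it improves the tour."""
    n = tour.size
    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for seg_len in (1, 2, 3):
            if n - seg_len < 3:
                continue
            i = 0
            while i + seg_len <= n - 1:
                prev = tour[i - 1]
                s0, s1 = tour[i], tour[i + seg_len - 1]
                nxt = tour[(i + seg_len) % n]
                gain_remove = (
                    dist[prev, s0] + dist[s1, nxt] - dist[prev, nxt]
                )
                if gain_remove > 1e-9:
                    # insertion points (between tour[j], tour[j+1]); both
                    # endpoints must lie outside the segment
                    j = np.arange(n)
                    mask = ((j < i - 1) | (j >= i + seg_len)) & ((j + 1) % n != i)
                    j = j[mask]
                    u = tour[j]
                    v = tour[(j + 1) % n]
                    cost_ins = dist[u, s0] + dist[s1, v] - dist[u, v]
                    best = int(np.argmin(cost_ins))
                    if cost_ins[best] < gain_remove - 1e-9:
                        seg = tour[i : i + seg_len].copy()
                        rest = np.concatenate([tour[:i], tour[i + seg_len :]])
                        pos = j[best]
                        pos_rest = pos - seg_len if pos >= i + seg_len else pos
                        tour = np.concatenate(
                            [rest[: pos_rest + 1], seg, rest[pos_rest + 1 :]]
                        )
                        improved = True
                        continue
                i += 1
    return tour


def order_clones(
    cluster: Sequence[str] | TSPInstance,
    overlaps: OverlapSet | None = None,
    seed: int = 0,
    restarts: int = 8,
    pr0: float | None = None,
    w0: float | None = None,
) -> ContigOrder:
    """Order a cluster by maximising ``W(O)`` (open-path TSP heuristic).

    Accepts either a prepared :class:`TSPInstance` or the cluster's clone
    ids plus the overlap set.  The best of ``restarts`` seeded
    nearest-neighbour + 2-opt/Or-opt runs is returned, with the
    orientation canonicalised (lexicographically smaller endpoint first).
    """
    if isinstance(cluster, TSPInstance):
        inst = cluster
    else:
        if overlaps is None:
            raise ValueError("overlaps required when passing raw clone ids")
        inst = tsp_distances(cluster, overlaps, pr0=pr0, w0=w0)
    n = len(inst.clone_ids)
    if n == 2:
        crit, gaps = _criterion(inst, np.array([0, 1]))
        return ContigOrder(list(inst.clone_ids), crit, gaps, inst.w0)
    # dummy-city trick: open path == closed tour through a free dummy node
    dim = n + 1
    dist = np.zeros((dim, dim))
    dist[:n, :n] = inst.dist
    rng = np.random.default_rng(seed)
    starts = list(rng.permutation(n)[: max(1, restarts)])
    best_perm: np.ndarray | None = None
    best_len = np.inf
    for start in starts:
        tour = np.concatenate([_nearest_neighbour(inst.dist, int(start)), [n]])
        tour = _two_opt(dist, tour)
        tour = _or_opt(dist, tour)
        tour = _two_opt(dist, tour)
        # cut the tour at the dummy to obtain the open path
        pos = int(np.flatnonzero(tour == n)[0])
        perm = np.concatenate([tour[pos + 1 :], tour[:pos]])
        length = float(inst.dist[perm[:-1], perm[1:]].sum())
        if length < best_len - 1e-12:
            best_len = length
            best_perm = perm
    assert best_perm is not None
    if inst.clone_ids[best_perm[0]] > inst.clone_ids[best_perm[-1]]:
        best_perm = best_perm[::-1]
    crit, gaps = _criterion(inst, best_perm)
    return ContigOrder([inst.clone_ids[i] for i in best_perm], crit, gaps, inst.w0)


def detect_gaps(
    order: ContigOrder | Sequence[str],
    overlaps: OverlapSet,
    pr0: float | None = None,
    metric: str | None = None,
) -> list[int]:
    """Positions ``i`` where ``Pr(O(i), O(i+1)) > Pr_0`` (non-significant)."""
    ids = order.order if isinstance(order, ContigOrder) else list(order)
    pr0 = pr0 if pr0 is not None else overlaps.cfg.pr0
    cut = -math.log10(pr0)
    return [
        i
        for i in range(len(ids) - 1)
        if overlaps.weight(ids[i], ids[i + 1], metric) <= cut
    ]


def jackknife(
    cluster: Sequence[str],
    db: FingerprintDB,
    cfg: MetricConfig,
    models: ModelCache | None = None,
    band_fraction: float = 0.95,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 2,
    w0: float | None = None,
) -> StabilityReport:
    """Jackknife stability of a cluster's order.

    Each replicate drops a random ``1 - band_fraction`` of the band
    *classes* from the universe (all their occurrences), recomputes the
    overlaps restricted to the kept bands against the same tail models,
    reorders, and tallies left/right neighbours after canonical
    orientation.  ``instability(c) = 1 - mean_side max_nbr freq``.
    """
    if replicates < 10:
        raise ValueError("at least 10 jackknife replicates are required")
    ids = sorted(cluster)
    index = db.ensure_abundances()
    if models is None:
        models = ModelCache(cfg, index)
    rng = np.random.default_rng(seed)
    n_classes = index.n_classes
    n_keep = max(1, int(math.floor(band_fraction * n_classes)))
    counts: dict[str, dict[str, dict[str, int]]] = {
        c: {"left": {}, "right": {}} for c in ids
    }
    sides_seen: dict[str, dict[str, int]] = {c: {"left": 0, "right": 0} for c in ids}
    for _ in range(replicates):
        kept = rng.choice(n_classes, size=n_keep, replace=False)
        keep = BandClassKeep(index, kept)
        ov = compute_overlaps(db, cfg, clone_ids=ids, models=models, keep=keep)
        inst = tsp_distances(ids, ov, w0=w0)
        order = order_clones(inst, seed=int(rng.integers(2**31)), restarts=restarts)
        for pos, clone in enumerate(order.order):
            if pos > 0:
                nbr = order.order[pos - 1]
                counts[clone]["left"][nbr] = counts[clone]["left"].get(nbr, 0) + 1
            sides_seen[clone]["left"] += 1
            if pos < len(order.order) - 1:
                nbr = order.order[pos + 1]
                counts[clone]["right"][nbr] = counts[clone]["right"].get(nbr, 0) + 1
            sides_seen[clone]["right"] += 1
    freq: dict[str, dict[str, dict[str, float]]] = {}
    instability: dict[str, float] = {}
    for clone in ids:
        freq[clone] = {}
        side_scores = []
        for side in ("left", "right"):
            freq[clone][side] = {
                nbr: cnt / replicates for nbr, cnt in counts[clone][side].items()
            }
            best = max(freq[clone][side].values(), default=0.0)
            side_scores.append(1.0 - best)
        instability[clone] = float(np.mean(side_scores))
    return StabilityReport(freq, instability, replicates, band_fraction)


def skeleton_order(
    order: ContigOrder,
    report: StabilityReport,
    threshold: float,
    overlaps: OverlapSet,
    seed: int = 0,
    restarts: int = 8,
    pr0: float | None = None,
    w0: float | None = None,
) -> ContigOrder:
    """Stable "skeleton" order: clones with instability above the
    threshold are removed, the rest reordered, and each removed clone
    attached to its most significantly overlapping kept neighbour."""
    removed = [c for c in order.order if report.instability.get(c, 0.0) > threshold]
    kept = [c for c in order.order if c not in removed]
    if len(kept) < 2 or not removed:
        out = ContigOrder(order.order, order.criterion, order.gaps, order.w0)
        return out
    new = order_clones(kept, overlaps, seed=seed, restarts=restarts, pr0=pr0, w0=w0)
    for c in removed:
        host = max(kept, key=lambda k: overlaps.weight(c, k))
        new.attached_buried.setdefault(host, []).append(c)
    return new
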