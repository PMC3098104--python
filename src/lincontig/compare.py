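"""Partition comparison statistics and ground-truth assembly evaluation.

Two clone partitions are compared with the Rand index (fraction of clone
pairs on which the partitions agree) and the mean-overlap statistic ``M``:
the average number of clusters of one partition that each cluster of the
other intersects (close to 1 for near-identical partitions).

For simulated libraries with known clone coordinates, assemblies are
scored directly against the genome: contigs mixing distant genomic
regions, genomic parts per contig, wrong clone orders, chimera exclusion,
and clone coverage of the contigs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import rand_score

from .ordering import ContigOrder
from .simulator import SimLibrary

__all__ = [
    "ComparisonStats",
    "rand_index",
    "mean_overlap",
    "compare_partitions",
    "evaluate_vs_truth",
]


@dataclass
class ComparisonStats:
    rand: float
    m_ab: float
    m_ba: float
    n_shared_clones: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rand_index": self.rand,
                    "mean_overlap_ab": self.m_ab,
                    "mean_overlap_ba": self.m_ba,
                    "n_shared_clones": self.n_shared_clones,
                },
                fh,
                indent=1,
            )


def _shared(p1: Mapping[str, str], p2: Mapping[str, str]) -> list[str]:
    return sorted(set(p1) & set(p2))


def rand_index(p1: Mapping[str, str], p2: Mapping[str, str]) -> float:
    """Rand index over the clones present in both partitions."""
    shared = _shared(p1, p2)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared clones to compare partitions")
    a = [p1[c] for c in shared]
    b = [p2[c] for c in shared]
    return float(rand_score(a, b))


def mean_overlap(
    p1: Mapping[str, str], p2: Mapping[str, str], min_cluster: int = 1
) -> float:
    """Mean number of P2 clusters intersected by each P1 cluster.

    ``min_cluster`` suppresses small P1 clusters (and singletons) from the
    average, the documented stand-in for the small-cluster-corrected
    variants of the statistic.
    """
    shared = set(_shared(p1, p2))
    clusters: dict[str, set[str]] = {}
    for c in shared:
        clusters.setdefault(p1[c], set()).add(c)
    counts = [
        len({p2[c] for c in members})
        for members in clusters.values()
        if len(members) >= min_cluster
    ]
    if not counts:
        raise ValueError("no clusters of the requested minimum size")
    return float(np.mean(counts))


def compare_partitions(
    p1: Mapping[str, str], p2: Mapping[str, str], min_cluster: int = 1
) -> ComparisonStats:
    return ComparisonStats(
        rand=rand_index(p1, p2),
        m_ab=mean_overlap(p1, p2, min_cluster),
        m_ba=mean_overlap(p2, p1, min_cluster),
        n_shared_clones=len(_shared(p1, p2)),
    )


# ---------------------------------------------------------------------------
# Ground-truth evaluation


def _genomic_parts(
    intervals: Sequence[tuple[int, int]], link_gap: float
) -> list[list[tuple[int, int]]]:
    """Group clone intervals into genomic parts: a new part starts when the
    next interval lies more than ``link_gap`` beyond the covered span."""
    ivs = sorted(intervals)
    parts: list[list[tuple[int, int]]] = []
    span_end = -np.inf
    for s, e in ivs:
        if parts and s <= span_end + link_gap:
            parts[-1].append((s, e))
            span_end = max(span_end, e)
        else:
            parts.append([(s, e)])
            span_end = e
    return parts


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    short = min(a[1] - a[0], b[1] - b[0])
    return max(inter, 0) / max(short, 1)


def _order_is_wrong(
    order: Sequence[str],
    spans: Mapping[str, tuple[int, int]],
    indistinct_frac: float = 0.8,
) -> bool:
    """True order violation beyond swaps of order-indistinguishable clones.

    An order counts as correct when it (or its reversal) can be sorted to
    true midpoint order using only adjacent swaps of near-identical
    (>80% overlapping) clones — equivalently, when every inverted pair
    overlaps by more than ``indistinct_frac`` of the shorter clone.
    """
    ids = [c for c in order if c in spans]
    if len(ids) < 3:
        return False
    mids = np.array([(spans[c][0] + spans[c][1]) / 2 for c in ids])

    def hard_violations(seq_ids: list[str], m: np.ndarray) -> int:
        bad = 0
        n = m.size
        for i in range(n):
            for j in range(i + 1, n):
                if m[j] < m[i] and _overlap_fraction(
                    spans[seq_ids[i]], spans[seq_ids[j]]
                ) <= indistinct_frac:
                    bad += 1
        return bad

    if hard_violations(ids, mids) == 0:
        return False
    return hard_violations(ids[::-1], mids[::-1]) > 0


def evaluate_vs_truth(
    contigs: Mapping[str, Sequence[str]] | Mapping[str, ContigOrder],
    lib: SimLibrary,
    orders: Mapping[str, Sequence[str]] | None = None,
    indistinct_frac: float = 0.8,
) -> dict:
    """Score an assembly against the simulator's ground truth.

    A contig is *chimeric* when its clones occupy genomic regions
    separated by more than one mean clone length with no covering chain;
    an order is *wrong* when neither it nor its reversal is monotone in
    true clone midpoints beyond adjacent swaps of clones overlapping more
    than ``indistinct_frac``.
    """
    members: dict[str, list[str]] = {}
    ord_map: dict[str, list[str]] = dict(
        {k: list(v) for k, v in (orders or {}).items()}
    )
    for cid, val in contigs.items():
        if isinstance(val, ContigOrder):
            members[cid] = list(val.members)  # ordered clones + attached buried
            ord_map.setdefault(cid, list(val.order))
        else:
            members[cid] = list(val)
    intervals = lib.intervals()
    if not intervals:
        raise ValueError("library has no retained clones / ground truth")
    link_gap = lib.config.mean_clone_len
    spans = {  # one span per clone: its largest genomic part
        c: max(ivs, key=lambda p: p[1] - p[0]) for c, ivs in intervals.items()
    }
    retained = set(intervals)
    chimeric_clones = {c.clone_id for c in lib.retained if c.chimeric}
    n_chim_ctg = 0
    parts_per_contig: list[int] = []
    n_ord_wrong = 0
    n_ordered = 0
    lengths_kbp: list[float] = []
    sizes: list[int] = []
    for cid, clones in members.items():
        present = [c for c in clones if c in retained]
        if not present:
            continue
        # non-chimeric clones' full intervals; chimeras contribute their parts
        ivs = [iv for c in present for iv in intervals[c]]
        parts = _genomic_parts(ivs, link_gap)
        parts_per_contig.append(len(parts))
        chim = len(parts) > 1
        n_chim_ctg += chim
        main = max(parts, key=lambda p: max(e for _, e in p) - min(s for s, _ in p))
        lengths_kbp.append((max(e for _, e in main) - min(s for s, _ in main)) / 1e3)
        sizes.append(len(present))
        order = ord_map.get(cid)
        if order and not chim:
            n_ordered += 1
            if _order_is_wrong(order, spans, indistinct_frac):
                n_ord_wrong += 1
    in_contigs = {c for clones in members.values() for c in clones if c in retained}
    chim_in_contigs = chimeric_clones & in_contigs
    return {
        "n_contigs": len(parts_per_contig),
        "n_contigs_chimeric": n_chim_ctg,
        "mean_parts_per_contig": float(np.mean(parts_per_contig)) if parts_per_contig else 0.0,
        "n_contigs_ordered": n_ordered,
        "n_contigs_misordered": n_ord_wrong,
        "frac_contigs_misordered": n_ord_wrong / n_ordered if n_ordered else 0.0,
        "n_clones_retained": len(retained),
        "n_clones_in_contigs": len(in_contigs),
        "frac_clones_in_contigs": len(in_contigs) / len(retained),
        "n_chimeric_retained": len(chimeric_clones),
        "n_chimeric_in_contigs": len(chim_in_contigs),
        "frac_chimeric_excluded": (
            1.0 - len(chim_in_contigs) / len(chimeric_clones)
            if chimeric_clones
            else 1.0
        ),
        "mean_clones_per_contig": float(np.mean(sizes)) if sizes else 0.0,
        "mean_contig_kbp": float(np.mean(lengths_kbp)) if lengths_kbp else 0.0,
    }
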