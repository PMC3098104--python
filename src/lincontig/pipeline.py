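"""End-to-end assembly pipeline.

Chains the stages in their canonical order: pairwise overlap p-values ->
parallel-path filtering and adaptive clustering -> linearity splitting ->
global-optimization ordering (optionally with jackknife stability and
skeleton reduction) -> contig elongation/merging -> MTP selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import networkx as nx

from .assembly import MTP, ElongationEvent, elongate, select_mtp
from .clustering import Partition, Schedule, adaptive_cluster
from .fingerprints import FingerprintDB, find_buried
from .graph import build_graph, linearity_check, split_nonlinear
from .metrics import MetricConfig, ModelCache, OverlapSet, compute_overlaps
from .ordering import ContigOrder, StabilityReport, jackknife, order_clones, skeleton_order

__all__ = ["PipelineOptions", "AssemblyResult", "default_metric_config", "assemble", "write_outputs"]


@dataclass
class PipelineOptions:
    """Tunable parameters of the assembly pipeline."""

    pr0: float = 1e-12
    stringency_step: float = 1e-3
    max_rounds: int = 10
    rs_bounds: tuple[int, int] = (6, 500)
    large_threshold: int = 500
    calibration_reps: int = 50_000
    prefilter_min_k: int = 5
    restarts: int = 4
    w0: float | None = None
    jackknife_replicates: int = 0  # 0 disables the stability stage
    jackknife_fraction: float = 0.95
    skeleton_threshold: float = 0.5
    detach_buried: bool = False  # detach buried clones before *clustering*
    buried_q: float = 0.90
    # detachment of buried/parallel clones before *ordering*: under the
    # default noise model a fully contained clone matches about
    # tau*(1-p_missing) ~ 0.89 of its bands; two binomial standard
    # deviations below that gives the threshold
    order_buried_q: float = 0.84
    seed: int = 0


@dataclass
class AssemblyResult:
    cfg: MetricConfig
    options: PipelineOptions
    overlaps: OverlapSet
    partition: Partition
    contigs: dict[str, ContigOrder]
    mtps: dict[str, MTP]
    tenpp_excluded: list[tuple[str, str]]
    branch_removed: list[str]
    events: list[ElongationEvent] = field(default_factory=list)
    stability: dict[str, StabilityReport] = field(default_factory=dict)

    def membership(self) -> dict[str, list[str]]:
        return {cid: list(co.members) for cid, co in self.contigs.items()}

    def contig_partition(self) -> dict[str, str]:
        return {c: cid for cid, co in self.contigs.items() for c in co.members}


def default_metric_config(
    db: FingerprintDB, options: PipelineOptions | None = None
) -> MetricConfig:
    """Metric configuration inferred from the database.

    The band-value universe ``G`` is the summed observed size range per
    band type; the abundance-weighted metric is the primary significance
    criterion.
    """
    options = options or PipelineOptions()
    types: dict[int, tuple[int, int]] = {}
    for fp in db:
        for t in fp.band_types:
            sizes = fp.sizes_of_type(t)
            lo, hi = int(sizes[0]), int(sizes[-1])
            if t in types:
                types[t] = (min(types[t][0], lo), max(types[t][1], hi))
            else:
                types[t] = (lo, hi)
    universe = sum(hi - lo + 1 for lo, hi in types.values()) or 18_000
    return MetricConfig(
        tolerance=db.tolerance,
        universe=universe,
        pr0=options.pr0,
        reps=options.calibration_reps,
        seed=options.seed,
        prefilter_min_k=options.prefilter_min_k,
        metrics=("sind",),
        primary="sind",
    )


def assemble(
    db: FingerprintDB,
    cfg: MetricConfig | None = None,
    options: PipelineOptions | None = None,
) -> AssemblyResult:
    """Run the full assembly pipeline on a fingerprint database."""
    if db.clone_count == 0:
        raise ValueError("empty fingerprint database")
    options = options or PipelineOptions()
    cfg = cfg or default_metric_config(db, options)
    models = ModelCache(cfg, db.ensure_abundances())
    overlaps = compute_overlaps(db, cfg, models=models)
    schedule = Schedule(
        pr0=cfg.pr0,
        step=options.stringency_step,
        max_rounds=options.max_rounds,
        large_threshold=options.large_threshold,
        rs_bounds=options.rs_bounds,
    )
    partition, pools = adaptive_cluster(
        db,
        overlaps,
        schedule,
        detach_buried=options.detach_buried,
        buried_q=options.buried_q,
    )
    # linearity splitting and ordering of the frozen clusters
    contigs: dict[str, ContigOrder] = {}
    branch_removed: list[str] = []
    loose: list[str] = []
    for cid, members in sorted(partition.rs_clusters().items()):
        g = build_graph(overlaps, pr0=cfg.pr0, clone_ids=members)
        pieces: list[list[str]] = []
        for comp in nx.connected_components(g.nx):
            sub = g.subgraph(comp)
            ok, _ = linearity_check(sub)
            if ok:
                pieces.append(sorted(comp))
            else:
                parts, removed = split_nonlinear(sub)
                branch_removed.extend(removed)
                pieces.extend(sorted(p.nx.nodes) for p in parts)
        for piece in pieces:
            if len(piece) < 2:
                loose.extend(piece)
                continue
            # detach buried/parallel clones before ordering; they re-attach
            # to their host and carry no order position of their own
            buried_pairs = find_buried(
                db, q=options.order_buried_q, clone_ids=piece
            )
            buried_map: dict[str, list[str]] = {}
            for b, host in buried_pairs:
                buried_map.setdefault(host, []).append(b)
            buried_set = {b for b, _ in buried_pairs}
            kept = [c for c in piece if c not in buried_set]
            if len(kept) < 2:
                kept = sorted(piece)
                buried_map = {}
                buried_set = set()
            order = order_clones(
                kept,
                overlaps,
                seed=options.seed,
                restarts=options.restarts,
                pr0=cfg.pr0,
                w0=options.w0,
            )
            for b, host in buried_pairs:
                if b in buried_set:
                    anchor = host if host in set(kept) else max(
                        kept, key=lambda k: overlaps.weight(b, k)
                    )
                    order.attached_buried.setdefault(anchor, []).append(b)
            contigs[min(piece)] = order
    # optional jackknife stability + skeleton reduction
    stability: dict[str, StabilityReport] = {}
    if options.jackknife_replicates >= 10:
        for cid in sorted(contigs):
            co = contigs[cid]
            rep = jackknife(
                co.order,
                db,
                cfg,
                models=models,
                band_fraction=options.jackknife_fraction,
                replicates=options.jackknife_replicates,
                seed=options.seed + 1,
                restarts=max(1, options.restarts // 2),
                w0=options.w0,
            )
            stability[cid] = rep
            slim = skeleton_order(
                co,
                rep,
                options.skeleton_threshold,
                overlaps,
                seed=options.seed,
                restarts=options.restarts,
                pr0=cfg.pr0,
                w0=options.w0,
            )
            kept_set = set(slim.order)
            for host, bb in co.attached_buried.items():
                anchor = host if host in kept_set else max(
                    kept_set, key=lambda k: overlaps.weight(bb[0], k)
                )
                slim.attached_buried.setdefault(anchor, []).extend(bb)
            contigs[cid] = slim
    # elongation/merging with re-admitted clones
    assigned = {c for co in contigs.values() for c in co.members}
    free = sorted(
        (set(overlaps.clone_ids) - assigned)
        | set(loose)
        | {c for c, _ in pools.excluded_vertices}
        | set(branch_removed)
    )
    marker_zones: dict[str, str] = {}
    contigs, events = elongate(
        contigs,
        overlaps,
        relaxed_pr0=cfg.pr0,
        free_clones=free,
        marker_zones=marker_zones,
        order_seed=options.seed,
    )
    # MTP selection on each contig's significant net
    mtps: dict[str, MTP] = {}
    for cid, co in sorted(contigs.items()):
        g = build_graph(overlaps, pr0=cfg.pr0, clone_ids=co.order)
        try:
            mtps[cid] = select_mtp(g, co)
        except ValueError:
            events.append(
                ElongationEvent("mtp-skipped", [cid], "terminal clones disconnected")
            )
    # final partition bookkeeping: contig membership wins
    for cid, co in contigs.items():
        for c in co.order:
            partition.assignment[c] = cid
            partition.state[c] = "CLUSTERED"
        for host, buried in co.attached_buried.items():
            for c in buried:
                partition.assignment[c] = cid
                partition.state[c] = "BURIED"
    return AssemblyResult(
        cfg=cfg,
        options=options,
        overlaps=overlaps,
        partition=partition,
        contigs=contigs,
        mtps=mtps,
        tenpp_excluded=list(pools.excluded_vertices),
        branch_removed=branch_removed,
        events=events,
        stability=stability,
    )


def write_outputs(result: AssemblyResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the pipeline's tables: partition, contig orders, MTPs,
    exclusion report, round history, and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "partition": out / "partition.tsv",
        "contigs": out / "contigs.tsv",
        "mtp": out / "mtp.tsv",
        "exclusions": out / "exclusions.tsv",
        "history": out / "history.jsonl",
        "summary": out / "summary.json",
    }
    result.partition.to_tsv(paths["partition"])
    with open(paths["contigs"], "w") as fh:
        fh.write("cluster_id\tposition\tclone_id\tgap_after\tinstability\tburied_in\n")
        for cid in sorted(result.contigs):
            co = result.contigs[cid]
            gaps = set(co.gaps)
            rep = result.stability.get(cid)
            for pos, clone in enumerate(co.order):
                inst = rep.instability.get(clone, 0.0) if rep else 0.0
                fh.write(
                    f"{cid}\t{pos}\t{clone}\t{int(pos in gaps)}\t{inst:.4f}\t-\n"
                )
                for buried in co.attached_buried.get(clone, []):
                    fh.write(f"{cid}\t{pos}\t{buried}\t0\t0.0000\t{clone}\n")
    with open(paths["mtp"], "w") as fh:
        fh.write("contig_id\tmtp_clones\tadjacent_log10p\n")
        for cid in sorted(result.mtps):
            m = result.mtps[cid]
            fh.write(
                f"{cid}\t{','.join(m.clones)}\t"
                f"{','.join(f'{p:.2f}' for p in m.adjacent_log10p)}\n"
            )
    with open(paths["exclusions"], "w") as fh:
        fh.write("element\tkind\treason\n")
        for clone, reason in result.tenpp_excluded:
            fh.write(f"{clone}\tvertex\t{reason}\n")
        for clone in result.branch_removed:
            fh.write(f"{clone}\tvertex\tbranching-node\n")
    result.partition.write_history(paths["history"])
    summary = {
        "n_clones": len(result.overlaps.clone_ids),
        "n_overlap_records": len(result.overlaps),
        "n_contigs": len(result.contigs),
        "n_clones_in_contigs": sum(len(co.members) for co in result.contigs.values()),
        "n_tenpp_excluded": len(result.tenpp_excluded),
        "n_branch_removed": len(result.branch_removed),
        "rounds": result.partition.history,
        "events": [
            {"kind": e.kind, "contigs": e.contigs, "detail": e.detail}
            for e in result.events
        ],
        "options": asdict(result.options),
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return paths
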