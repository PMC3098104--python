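"""In-silico BAC library simulation from a genome sequence.

The simulator emulates the construction of a high-information-content
fingerprinting (HICF) library:

1. The genome is digested in silico with a boundary enzyme (HindIII);
   clones are intervals between boundary sites.  A clone picks a uniform
   start site, a random direction, and a site count
   ``h = floor(Normal(a, sigma^2))`` with ``a = 120 kbp * lambda`` and
   ``sigma = 30 kbp * lambda`` where ``lambda`` is the boundary-site
   density, so clone lengths average ~120 kbp with ~30 kbp nominal spread.
2. With probability ``p_chimer`` a clone is chimeric: the union of the
   clone and one (occasionally more) additional independently drawn clone.
3. Bands: within a clone, fragments are delimited by the sites of K
   protruding-end enzymes (BamHI, EcoRI, XbaI, XhoI), a blunt-end enzyme
   (HaeIII), and the clone ends.  A fragment yields one band per
   *distinct* protruding-end enzyme bounding it — a fragment bounded by
   two different protruding enzymes appears twice in the fingerprint, one
   bounded only by HaeIII/clone ends not at all.  Band lengths outside
   [50, 500] bp are discarded.
4. Observation noise: each band length gains a uniform error from
   ``(-eps, eps)`` with probability ``p_eps`` or ``(-3 eps, 3 eps)``
   otherwise, is scaled x30 and rounded (FPC units; tolerance 12), and is
   lost with probability ``p_missing``.  Clones with fewer than 50 or more
   than 250 observed bands are dropped.

Ground truth (genome coordinates, true bands, chimera structure) is kept
for every clone so assemblies can be scored against reality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fingerprints import Fingerprint, FingerprintDB, write_band_tsv, write_sizes

__all__ = [
    "SimConfig",
    "SimClone",
    "SimLibrary",
    "random_genome",
    "find_sites",
    "simulate_clones",
    "fingerprint_true",
    "observe",
    "tolerance_match_prob",
    "summarize",
    "write_fpc",
    "encode_band",
]

BASES = "ACGT"


@dataclass
class SimConfig:
    """Parameters of the library simulation (defaults: the study conditions)."""

    boundary_enzyme: str = "AAGCTT"  # HindIII
    protruding_enzymes: tuple[tuple[str, str], ...] = (
        ("BamHI", "GGATCC"),
        ("EcoRI", "GAATTC"),
        ("XbaI", "TCTAGA"),
        ("XhoI", "CTCGAG"),
    )
    blunt_enzyme: str = "GGCC"  # HaeIII
    mean_clone_len: float = 120_000.0  # bp
    sd_clone_len: float = 30_000.0  # bp
    p_chimer: float = 0.05
    band_min: int = 50  # bp
    band_max: int = 500  # bp
    n_min: int = 50  # observed bands per retained clone
    n_max: int = 250
    eps: float = 0.2  # narrow error half-width (bp, pre-scaling)
    p_eps: float = 0.90
    scale: int = 30  # FPC scaling of band lengths
    type_offset: int = 5000
    p_missing: float = 0.05
    n_clones: int = 1000
    n_markers: int = 0  # optional marker anchors scattered on the genome
    gc: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_chimer, self.p_eps, self.p_missing):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.band_min >= self.band_max:
            raise ValueError("band window must satisfy L_min < L_max")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def k_types(self) -> int:
        return len(self.protruding_enzymes)

    @property
    def tolerance(self) -> int:
        """Scored-size tolerance after scaling: t = scale * 2 * eps."""
        return int(round(self.scale * 2 * self.eps))


@dataclass
class SimClone:
    """One simulated clone with its ground truth."""

    clone_id: str
    parts: list[tuple[int, int, int]]  # (start bp, end bp, strand)
    true_bands: list[tuple[int, int]] = field(default_factory=list)  # (type, bp length)
    observed: Fingerprint | None = None
    dropped_reason: str | None = None

    @property
    def chimeric(self) -> bool:
        return len(self.parts) >= 2

    @property
    def length(self) -> int:
        return sum(e - s for s, e, _ in self.parts)

    @property
    def retained(self) -> bool:
        return self.observed is not None


@dataclass
class SimLibrary:
    """Simulated clones plus the site index and ground truth."""

    genome_id: str
    length: int
    boundary_sites: np.ndarray  # with 0 and L sentinels
    sites: dict[str, np.ndarray]  # cutter name -> positions (no sentinels)
    clones: list[SimClone]
    config: SimConfig
    markers: dict[str, int] = field(default_factory=dict)  # marker id -> genome pos

    @property
    def retained(self) -> list[SimClone]:
        return [c for c in self.clones if c.retained]

    @property
    def coverage(self) -> float:
        return sum(c.length for c in self.clones) / self.length

    def to_db(self) -> FingerprintDB:
        """Fingerprint database of the retained clones (with markers)."""
        db = FingerprintDB(tolerance=self.config.tolerance)
        for c in self.retained:
            db.add(c.observed)
        return db

    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {c.clone_id: [(s, e) for s, e, _ in c.parts] for c in self.retained}

    def true_regions(self, which: str = "retained") -> list[tuple[int, int]]:
        """Maximal genome segments covered by (retained) clone intervals."""
        clones = self.retained if which == "retained" else self.clones
        ivs = sorted((s, e) for c in clones for s, e, _ in c.parts)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def true_partition(self) -> dict[str, str]:
        """Clone -> region label (a chimera is assigned its largest part)."""
        regions = self.true_regions()
        starts = np.array([s for s, _ in regions])
        out: dict[str, str] = {}
        for c in self.retained:
            s, e, _ = max(c.parts, key=lambda p: p[1] - p[0])
            idx = int(np.searchsorted(starts, s, side="right") - 1)
            out[c.clone_id] = f"region{idx:03d}"
        return out


def random_genome(length: int, seed: int = 0, gc: float = 0.44) -> str:
    """I.i.d. random genome at the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return draws.tobytes().decode("ascii")


def write_fasta(seq: str, path: str | Path, name: str = "synthetic") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as (name, sequence)."""
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    break
                name = line[1:].split()[0] or "seq"
            elif name is not None:
                chunks.append(line.upper())
    if name is None:
        raise ValueError(f"no FASTA record found in {path}")
    return name, "".join(chunks)


def find_sites(seq: str, motif: str) -> np.ndarray:
    """All (possibly overlapping) start positions of the motif."""
    positions: list[int] = []
    start = seq.find(motif)
    while start != -1:
        positions.append(start)
        start = seq.find(motif, start + 1)
    return np.asarray(positions, dtype=np.int64)


def boundary_index(seq: str, motif: str) -> np.ndarray:
    """Boundary-enzyme site list supplemented with the 0 and L sentinels."""
    sites = find_sites(seq, motif)
    return np.concatenate([[0], sites, [len(seq)]])


def encode_band(band_type: int, scaled_size: int, type_offset: int = 5000) -> int:
    """FPC-file encoding of a typed band: size plus ``(k-1)*offset``."""
    return scaled_size + (band_type - 1) * type_offset


def fingerprint_true(
    parts: Sequence[tuple[int, int, int]],
    sites: Mapping[str, np.ndarray],
    cfg: SimConfig,
) -> list[tuple[int, int]]:
    """True typed bands of a clone (before the length window is applied
    the fragment set is exact; bands outside [band_min, band_max] bp are
    dropped here as in the wet protocol).

    Within each clone part the sequence is cut at every protruding-end and
    blunt-end site plus the part ends; each fragment contributes one band
    per distinct protruding-end enzyme bounding it.
    """
    bands: list[tuple[int, int]] = []
    enzyme_names = [name for name, _ in cfg.protruding_enzymes]
    for start, end, _strand in parts:
        cuts: dict[int, int] = {start: 0, end: 0}  # position -> bounding kind
        for k, name in enumerate(enzyme_names, start=1):
            pos = sites[name]
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="right"))
            for p in pos[lo:hi].tolist():
                cuts[p] = k  # protruding sites take precedence over ends
        blunt = sites["blunt"]
        lo = int(np.searchsorted(blunt, start, side="left"))
        hi = int(np.searchsorted(blunt, end, side="right"))
        for p in blunt[lo:hi].tolist():
            cuts.setdefault(p, 0)
        positions = sorted(cuts)
        for a, b in zip(positions, positions[1:]):
            frag = b - a
            if frag < cfg.band_min or frag > cfg.band_max:
                continue
            for k in {cuts[a], cuts[b]} - {0}:
                bands.append((k, frag))
    bands.sort()
    return bands


def observe(
    true_bands: Sequence[tuple[int, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> tuple[Fingerprint | None, str | None]:
    """Noisy observation of a clone's true bands.

    Returns the observed fingerprint, or ``(None, reason)`` when the clone
    is dropped by the band-count filter.
    """
    observed: list[tuple[int, int]] = []
    for k, length in true_bands:
        if rng.random() < cfg.p_missing:
            continue
        if rng.random() < cfg.p_eps:
            err = rng.uniform(-cfg.eps, cfg.eps)
        else:
            err = rng.uniform(-3 * cfg.eps, 3 * cfg.eps)
        observed.append((k, int(round(cfg.scale * (length + err)))))
    n = len(observed)
    if n < cfg.n_min:
        return None, f"too-few-bands({n})"
    if n > cfg.n_max:
        return None, f"too-many-bands({n})"
    return Fingerprint(clone_id, observed), None


def tolerance_match_prob(eps: float, t: float, p_eps: float) -> float:
    """Closed-form probability tau that two observations of the same band
    differ by less than the tolerance ``t`` under the two-component
    uniform error model (valid for ``0 < t <= 2 eps``)."""
    if not 0 < t <= 2 * eps:
        raise ValueError("formula requires 0 < t <= 2*eps")
    p3 = 1.0 - p_eps
    return (
        p_eps**2 * (1 - (1 - t / (2 * eps)) ** 2)
        + p3**2 * (1 - (1 - t / (6 * eps)) ** 2)
        + 2 * p_eps * p3 * (t / (3 * eps))
    )


def _draw_part(
    r: np.ndarray, a: float, sigma: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """One regular clone part: uniform start site, random direction,
    normal site-count length; degenerate draws are retried."""
    n_plus_1 = r.size - 1
    for _ in range(1000):
        i_start = int(rng.integers(0, n_plus_1 + 1))
        s = 1 if rng.random() < 0.5 else -1
        h = int(math.floor(rng.normal(a, sigma)))
        if h <= 0:
            continue
        i_end = min(max(i_start + s * h, 0), n_plus_1)
        if r[i_end] == r[i_start]:
            continue
        lo, hi = sorted((int(r[i_start]), int(r[i_end])))
        return lo, hi, s
    raise RuntimeError("could not draw a non-degenerate clone part")


def simulate_clones(
    seq: str,
    cfg: SimConfig,
    genome_id: str = "synthetic",
) -> SimLibrary:
    """Simulate the full library from a genome sequence.

    Builds the site index for every cutter, samples ``cfg.n_clones``
    clones (chimeric with probability ``p_chimer``, as unions of
    independently drawn regular clones), fingerprints them, applies
    observation noise and the band-count filter, and records ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    r = boundary_index(seq, cfg.boundary_enzyme)
    if r.size < 4:
        raise ValueError("need at least 2 boundary-enzyme sites to sample clones")
    sites: dict[str, np.ndarray] = {
        name: find_sites(seq, motif) for name, motif in cfg.protruding_enzymes
    }
    sites["blunt"] = find_sites(seq, cfg.blunt_enzyme)
    L = len(seq)
    lam = (r.size - 1) / L  # (N + 1) / L
    a = cfg.mean_clone_len * lam
    sigma = cfg.sd_clone_len * lam
    width = len(str(max(cfg.n_clones, 1)))
    clones: list[SimClone] = []
    for i in range(cfg.n_clones):
        parts = [_draw_part(r, a, sigma, rng)]
        while rng.random() < cfg.p_chimer and len(parts) < 4:
            parts.append(_draw_part(r, a, sigma, rng))
        clone_id = f"c{i:0{width}d}"
        clone = SimClone(clone_id, parts)
        clone.true_bands = fingerprint_true(parts, sites, cfg)
        clone.observed, clone.dropped_reason = observe(
            clone.true_bands, cfg, rng, clone_id
        )
        clones.append(clone)
    lib = SimLibrary(genome_id, L, r, sites, clones, cfg)
    if cfg.n_markers > 0:
        positions = rng.integers(0, L, size=cfg.n_markers)
        lib.markers = {f"m{j:04d}": int(p) for j, p in enumerate(sorted(positions))}
        for c in lib.retained:
            hit = {
                mk
                for mk, p in lib.markers.items()
                if any(s <= p < e for s, e, _ in c.parts)
            }
            if hit:
                c.observed = c.observed.with_markers(hit)
    return lib


def read_ground_truth(sim_dir: str | Path) -> SimLibrary:
    """Reconstruct a coordinates-only library from a simulation directory.

    Reads ``ground_truth.tsv`` plus ``sim_config.json``/``summary.json``
    written by :func:`write_fpc` (and the CLI).  The returned library
    carries clone coordinates, retention and chimera structure — enough
    for ground-truth evaluation — but no sequences or band lists.
    """
    sim_dir = Path(sim_dir)
    cfg = SimConfig()
    cfg_path = sim_dir / "sim_config.json"
    if cfg_path.exists():
        payload = json.loads(cfg_path.read_text())
        payload.pop("protruding_enzymes", None)
        cfg = SimConfig(**{k: v for k, v in payload.items() if k in SimConfig.__dataclass_fields__})
    length = 0
    summary_path = sim_dir / "summary.json"
    if summary_path.exists():
        length = int(json.loads(summary_path.read_text()).get("sequence_length", 0))
    clones: list[SimClone] = []
    with open(sim_dir / "ground_truth.tsv") as fh:
        header = fh.readline()
        for line in fh:
            clone_id, retained, reason, _chim, parts_s = line.rstrip("\n").split("\t")
            parts = []
            for token in parts_s.split(";"):
                span, strand = token.split(":")
                s, e = span.split("-")
                parts.append((int(s), int(e), int(strand)))
            clone = SimClone(clone_id, parts)
            if retained == "1":
                clone.observed = Fingerprint(clone_id, [(1, 1)])  # placeholder
            else:
                clone.dropped_reason = reason
            clones.append(clone)
    length = length or max(e for c in clones for _, e, _ in c.parts)
    return SimLibrary("reconstructed", length, np.array([0, length]), {}, clones, cfg)


def summarize(lib: SimLibrary) -> dict:
    """Basic library characteristics (counts, means, coverage, chimeras)."""
    cfg = lib.config
    clones = lib.clones
    retained = lib.retained
    true_band_lengths = [l for c in clones for _, l in c.true_bands]
    obs_counts = [c.observed.n for c in retained]
    obs_sizes = [b.size for c in retained for b in c.observed.bands]
    chim_counts = {2: 0, 3: 0, 4: 0}
    for c in clones:
        if c.chimeric:
            chim_counts[min(len(c.parts), 4)] += 1
    n_sites = lib.boundary_sites.size - 2
    return {
        "sequence_length": lib.length,
        "n_boundary_sites": n_sites,
        "mean_site_spacing": lib.length / max(n_sites + 1, 1),
        "n_true_bands": sum(len(c.true_bands) for c in clones),
        "mean_true_band_bp": float(np.mean(true_band_lengths)) if true_band_lengths else 0.0,
        "n_mean_true": float(np.mean([len(c.true_bands) for c in clones])) if clones else 0.0,
        "n_mean_obs": float(np.mean(obs_counts)) if obs_counts else 0.0,
        "mean_clone_len_true_kbp": float(np.mean([c.length for c in clones])) / 1e3 if clones else 0.0,
        "sd_clone_len_true_kbp": float(np.std([c.length for c in clones])) / 1e3 if clones else 0.0,
        "mean_clone_len_obs_kbp": float(np.mean([c.length for c in retained])) / 1e3 if retained else 0.0,
        "mean_band_obs_scaled": float(np.mean(obs_sizes)) if obs_sizes else 0.0,
        "mean_band_obs_bp": float(np.mean(obs_sizes)) / cfg.scale if obs_sizes else 0.0,
        "n_clones_simulated": len(clones),
        "n_clones_retained": len(retained),
        "coverage": lib.coverage,
        "n_chimeric": sum(chim_counts.values()),
        "chimera_parts_histogram": chim_counts,
        "tolerance": cfg.tolerance,
    }


def write_fpc(lib: SimLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Emit the FPC-format sizes file plus ground-truth tables.

    Writes ``library.sizes`` (offset-encoded band sizes), ``markers.tsv``
    (if any), ``ground_truth.tsv`` (clone coordinates, strand, chimera
    structure, drop reasons), ``true_partition.tsv`` and ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sizes": out / "library.sizes",
        "bands_tsv": out / "library.bands.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "true_partition": out / "true_partition.tsv",
        "summary": out / "summary.json",
    }
    db = lib.to_db()
    # FPC-style file: offset-encoded values.  With scaled sizes above the
    # 5000 offset the encoding folds band types together, so the typed TSV
    # alongside is the lossless representation.
    with open(paths["sizes"], "w") as fh:
        fh.write(f"// simulated HICF sizes file, tolerance {lib.config.tolerance}\n")
        write_sizes(db, fh, use_offsets=True)
    write_band_tsv(db, paths["bands_tsv"])
    with open(paths["ground_truth"], "w") as fh:
        fh.write("clone_id\tretained\treason\tchimeric\tparts\n")
        for c in lib.clones:
            parts = ";".join(f"{s}-{e}:{st:+d}" for s, e, st in c.parts)
            fh.write(
                f"{c.clone_id}\t{int(c.retained)}\t{c.dropped_reason or '-'}\t"
                f"{int(c.chimeric)}\t{parts}\n"
            )
    with open(paths["true_partition"], "w") as fh:
        fh.write("clone_id\tregion\n")
        for clone, region in sorted(lib.true_partition().items()):
            fh.write(f"{clone}\t{region}\n")
    with open(paths["summary"], "w") as fh:
        json.dump(summarize(lib), fh, indent=1, sort_keys=True)
    if lib.markers:
        paths["markers"] = out / "markers.tsv"
        with open(paths["markers"], "w") as fh:
            fh.write("clone_id\tmarker_id\n")
            for c in lib.retained:
                for mk in sorted(c.observed.markers):
                    fh.write(f"{c.clone_id}\t{mk}\n")
    return paths
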