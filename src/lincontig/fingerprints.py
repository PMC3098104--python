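"""Clone fingerprints: typed band multisets, tolerance matching, abundances.

A BAC clone's restriction fingerprint is a multiset of *bands*.  Each band
has an integer ``band_type`` (dye/enzyme class, 1..K) and an integer scored
``size``.  Two bands can match only if they have the same type and their
sizes differ by at most the database tolerance ``t``.

The module also provides

* readers/writers for the FPC "sizes" dialect (where the band type may be
  encoded as a ``(k-1)*5000`` offset added to the size) and a plain TSV
  alternative,
* maximum-likelihood band-abundance estimation used by the
  abundance-weighted overlap metric, and
* detection of "buried" clones (fingerprints almost contained in another
  clone's fingerprint).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TYPE_OFFSET",
    "BandKey",
    "Fingerprint",
    "FingerprintDB",
    "BandClassIndex",
    "shared_bands",
    "shared_band_count",
    "estimate_abundances",
    "find_buried",
    "read_sizes",
    "write_sizes",
    "read_band_tsv",
    "write_band_tsv",
    "read_markers",
]

#: Size offset separating band types in offset-encoded sizes files.
TYPE_OFFSET = 5000


@dataclass(frozen=True, order=True)
class BandKey:
    """One scored band: dye/enzyme class plus scored fragment size."""

    band_type: int
    size: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"band size must be positive, got {self.size}")
        if self.band_type < 1:
            raise ValueError(f"band_type must be >= 1, got {self.band_type}")


class Fingerprint:
    """A clone's fingerprint: a sorted multiset of bands plus marker anchors.

    Bands are stored per type as sorted integer arrays so that tolerance
    matching can run as a two-pointer sweep.
    """

    __slots__ = ("clone_id", "markers", "_by_type")

    def __init__(
        self,
        clone_id: str,
        bands: Iterable[tuple[int, int]] | Iterable[BandKey],
        markers: Iterable[str] = (),
    ) -> None:
        self.clone_id = str(clone_id)
        by_type: dict[int, list[int]] = {}
        for b in bands:
            if isinstance(b, BandKey):
                k, s = b.band_type, b.size
            else:
                k, s = int(b[0]), int(b[1])
            if s <= 0:
                raise ValueError(f"clone {clone_id}: band size {s} <= 0")
            if k < 1:
                raise ValueError(f"clone {clone_id}: band type {k} < 1")
            by_type.setdefault(k, []).append(s)
        self._by_type: dict[int, np.ndarray] = {
            k: np.asarray(sorted(v), dtype=np.int64) for k, v in sorted(by_type.items())
        }
        self.markers: frozenset[str] = frozenset(str(m) for m in markers)

    @property
    def n(self) -> int:
        """Number of bands n(c)."""
        return sum(a.size for a in self._by_type.values())

    @property
    def bands(self) -> list[BandKey]:
        """All bands sorted by (band_type, size)."""
        return [
            BandKey(k, int(s)) for k in sorted(self._by_type) for s in self._by_type[k]
        ]

    def sizes_of_type(self, band_type: int) -> np.ndarray:
        return self._by_type.get(band_type, np.empty(0, dtype=np.int64))

    @property
    def band_types(self) -> list[int]:
        return sorted(self._by_type)

    def with_markers(self, markers: Iterable[str]) -> "Fingerprint":
        fp = Fingerprint.__new__(Fingerprint)
        fp.clone_id = self.clone_id
        fp._by_type = self._by_type
        fp.markers = frozenset(self.markers) | frozenset(markers)
        return fp

    def restricted(self, keep: "BandClassKeep") -> "Fingerprint":
        """Fingerprint with only the bands whose band class is kept.

        Used by the jackknife resampling: whole band *classes* are dropped
        from the universe, not individual per-clone bands.
        """
        fp = Fingerprint.__new__(Fingerprint)
        fp.clone_id = self.clone_id
        fp.markers = self.markers
        fp._by_type = {
            k: sizes[keep.mask(k, sizes)]
            for k, sizes in self._by_type.items()
        }
        fp._by_type = {k: v for k, v in fp._by_type.items() if v.size}
        return fp

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"Fingerprint({self.clone_id!r}, n={self.n}, markers={len(self.markers)})"


def shared_bands(
    fp1: Fingerprint, fp2: Fingerprint, tolerance: int
) -> tuple[int, list[tuple[BandKey, BandKey]]]:
    """Greedy one-to-one matching of two fingerprints under a tolerance.

    Per band type the two sorted size lists are swept with two pointers; a
    band participates in at most one match.  Returns the shared-band count
    ``k`` and the matched band pairs.  The count is symmetric in the two
    fingerprints.
    """
    pairs: list[tuple[BandKey, BandKey]] = []
    for k in fp1.band_types:
        a = fp1.sizes_of_type(k)
        b = fp2.sizes_of_type(k)
        i = j = 0
        na, nb = a.size, b.size
        while i < na and j < nb:
            d = int(a[i]) - int(b[j])
            if abs(d) <= tolerance:
                pairs.append((BandKey(k, int(a[i])), BandKey(k, int(b[j]))))
                i += 1
                j += 1
            elif d < 0:
                i += 1
            else:
                j += 1
    return len(pairs), pairs


def shared_band_count(fp1: Fingerprint, fp2: Fingerprint, tolerance: int) -> int:
    """Shared-band count only (fast path of :func:`shared_bands`)."""
    total = 0
    for k, a in fp1._by_type.items():
        b = fp2._by_type.get(k)
        if b is None:
            continue
        i = j = 0
        na, nb = a.size, b.size
        av = a.tolist()
        bv = b.tolist()
        while i < na and j < nb:
            d = av[i] - bv[j]
            if d < -tolerance:
                i += 1
            elif d > tolerance:
                j += 1
            else:
                total += 1
                i += 1
                j += 1
    return total


class BandClassKeep:
    """Subset of band classes retained in a jackknife replicate."""

    def __init__(self, index: "BandClassIndex", kept_class_ids: np.ndarray) -> None:
        self._index = index
        self._kept = np.zeros(index.n_classes, dtype=bool)
        self._kept[kept_class_ids] = True

    def mask(self, band_type: int, sizes: np.ndarray) -> np.ndarray:
        cls = self._index.class_of(band_type, sizes)
        return self._kept[cls]


class BandClassIndex:
    """Band classes pooled along the size axis, with abundance estimates.

    Per band type the sorted distinct observed sizes are clustered greedily:
    a new class starts whenever the gap to the previous distinct size
    exceeds the tolerance.  For class ``b``, ``pi_b`` is the fraction of
    clones carrying a band of the class and ``f_b`` the maximum-likelihood
    abundance approximation ``n_mean^-1 * pi_b / (1 - pi_b)``, capped at 1.
    """

    def __init__(
        self,
        boundaries: Mapping[int, np.ndarray],
        class_offset: Mapping[int, int],
        pi: np.ndarray,
        f: np.ndarray,
        representative: list[BandKey],
    ) -> None:
        self._boundaries = dict(boundaries)  # per type: first size of each class
        self._offset = dict(class_offset)  # per type: global id of its class 0
        self.pi = pi
        self.f = f
        self.representative = representative

    @property
    def n_classes(self) -> int:
        return self.f.size

    def class_of(self, band_type: int, sizes: np.ndarray | int) -> np.ndarray:
        bounds = self._boundaries[band_type]
        idx = np.searchsorted(bounds, np.asarray(sizes), side="right") - 1
        return idx + self._offset[band_type]

    def f_of(self, band_type: int, sizes: np.ndarray | int) -> np.ndarray:
        return self.f[self.class_of(band_type, sizes)]

    def as_mapping(self) -> dict[BandKey, float]:
        """Representative BandKey of each class -> abundance f_b."""
        return {rep: float(fb) for rep, fb in zip(self.representative, self.f)}


class FingerprintDB:
    """Collection of clone fingerprints sharing one tolerance."""

    def __init__(self, clones: Iterable[Fingerprint] = (), tolerance: int = 12) -> None:
        self.tolerance = int(tolerance)
        self._clones: dict[str, Fingerprint] = {}
        self.abundance: BandClassIndex | None = None
        for fp in clones:
            self.add(fp)

    def add(self, fp: Fingerprint) -> None:
        if fp.clone_id in self._clones:
            raise ValueError(f"duplicate clone id {fp.clone_id!r}")
        self._clones[fp.clone_id] = fp
        self.abundance = None

    def __len__(self) -> int:
        return len(self._clones)

    def __iter__(self) -> Iterator[Fingerprint]:
        return iter(self._clones.values())

    def __contains__(self, clone_id: str) -> bool:
        return clone_id in self._clones

    def __getitem__(self, clone_id: str) -> Fingerprint:
        return self._clones[clone_id]

    @property
    def clone_ids(self) -> list[str]:
        return list(self._clones)

    @property
    def clone_count(self) -> int:
        return len(self._clones)

    @property
    def n_mean(self) -> float:
        if not self._clones:
            return 0.0
        return float(np.mean([fp.n for fp in self]))

    def attach_markers(self, anchors: Mapping[str, Iterable[str]]) -> None:
        """Attach marker ids (clone -> markers) to the stored fingerprints."""
        for clone_id, markers in anchors.items():
            if clone_id in self._clones:
                self._clones[clone_id] = self._clones[clone_id].with_markers(markers)

    def ensure_abundances(self) -> BandClassIndex:
        if self.abundance is None:
            self.abundance = estimate_abundances(self)
        return self.abundance


def estimate_abundances(db: FingerprintDB) -> BandClassIndex:
    """Estimate band-class abundances ``f_b`` from the whole database.

    ``pi_b = N_b / N`` where ``N_b`` counts clones with a band in class
    ``b``; ``f_b = min(1, n_mean^-1 * pi_b/(1-pi_b))``, with ``pi_b = 1``
    capped by substituting ``N`` for the odds ratio.
    """
    if db.clone_count < 1:
        raise ValueError("cannot estimate abundances from an empty database")
    t = db.tolerance
    n_clones = db.clone_count
    n_mean = db.n_mean
    all_types = sorted({k for fp in db for k in fp.band_types})
    boundaries: dict[int, np.ndarray] = {}
    offsets: dict[int, int] = {}
    pi_parts: list[np.ndarray] = []
    reps: list[BandKey] = []
    offset = 0
    for k in all_types:
        sizes = np.unique(np.concatenate([db[c].sizes_of_type(k) for c in db.clone_ids]))
        # greedy pooling: new class when gap to previous distinct size > t
        starts = np.flatnonzero(np.diff(sizes, prepend=sizes[0] - t - 1) > t)
        bounds = sizes[starts]
        boundaries[k] = bounds
        offsets[k] = offset
        n_cls = bounds.size
        counts = np.zeros(n_cls, dtype=np.int64)
        for fp in db:
            s = fp.sizes_of_type(k)
            if not s.size:
                continue
            cls = np.unique(np.searchsorted(bounds, s, side="right") - 1)
            counts[cls] += 1
        pi_parts.append(counts / n_clones)
        # representative: first size of each class, offset back to a BandKey
        reps.extend(BandKey(k, int(b)) for b in bounds)
        offset += n_cls
    pi = np.concatenate(pi_parts) if pi_parts else np.empty(0)
    odds = np.where(pi >= 1.0, float(n_clones), pi / np.clip(1.0 - pi, 1e-300, None))
    f = np.minimum(1.0, odds / max(n_mean, 1e-300))
    return BandClassIndex(boundaries, offsets, pi, f, reps)


def find_buried(
    db: FingerprintDB,
    q: float = 0.90,
    clone_ids: Sequence[str] | None = None,
) -> list[tuple[str, str]]:
    """Detect buried clones: ``shared(c_i, c_j) / n(c_i) >= q`` with
    ``n(c_i) <= n(c_j)``.

    Returns ``(buried, host)`` pairs.  Mutual burial (identical band
    counts) is resolved lexicographically: the smaller clone id is buried
    in the larger.  Each clone is reported buried at most once (in its
    best-covering host).
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    ids = sorted(clone_ids if clone_ids is not None else db.clone_ids)
    t = db.tolerance
    best: dict[str, tuple[float, str]] = {}
    for i, ci in enumerate(ids):
        fi = db[ci]
        for cj in ids[i + 1 :]:
            fj = db[cj]
            k = shared_band_count(fi, fj, t)
            if k == 0:
                continue
            small, large = (ci, cj) if (fi.n, ci) <= (fj.n, cj) else (cj, ci)
            frac = k / db[small].n
            if frac >= q and frac > best.get(small, (-1.0, ""))[0]:
                best[small] = (frac, large)
    return sorted((buried, host) for buried, (_, host) in best.items())


# ---------------------------------------------------------------------------
# I/O


def read_sizes(
    path: str | Path | io.TextIOBase,
    k_types: int = 4,
    tolerance: int = 12,
    use_offsets: bool = True,
) -> FingerprintDB:
    """Read an FPC-style sizes file.

    Each record is a header line ``cloneName bandCount`` followed by
    whitespace-separated integer sizes terminated by ``-1``.  With
    ``use_offsets`` the band type is decoded as ``1 + size // 5000`` and the
    size reduced modulo the 5000 offset; otherwise every band is type 1.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh = path
    try:
        tokens: list[str] = []
        for line in fh:
            line = line.split("//")[0]
            tokens.extend(line.split())
    finally:
        if close:
            fh.close()
    db = FingerprintDB(tolerance=tolerance)
    pos = 0
    while pos < len(tokens):
        name = tokens[pos]
        if pos + 1 >= len(tokens):
            raise ValueError(f"truncated record for clone {name!r}")
        try:
            declared = int(tokens[pos + 1])
        except ValueError as exc:
            raise ValueError(f"bad band count for clone {name!r}: {tokens[pos+1]!r}") from exc
        pos += 2
        sizes: list[int] = []
        while pos < len(tokens):
            v = int(tokens[pos])
            pos += 1
            if v == -1:
                break
            sizes.append(v)
        else:
            raise ValueError(f"record for clone {name!r} not terminated by -1")
        if len(sizes) != declared:
            raise ValueError(
                f"clone {name!r}: declared {declared} bands but parsed {len(sizes)}"
            )
        bands = []
        for s in sizes:
            if s <= 0:
                raise ValueError(f"clone {name!r}: band size {s} <= 0")
            if use_offsets:
                # the decoded "type" is the 5000-wide encoding bucket; with
                # scaled sizes above 5000 buckets beyond K can occur and are
                # kept as-is (matching within buckets equals matching on the
                # raw encoded values except at rare bucket boundaries)
                k = 1 + (s - 1) // TYPE_OFFSET
                bands.append((k, s - (k - 1) * TYPE_OFFSET))
            else:
                bands.append((1, s))
        if name in db:
            raise ValueError(f"duplicate clone id {name!r}")
        db.add(Fingerprint(name, bands))
    return db


def write_sizes(
    db: FingerprintDB, path: str | Path | io.TextIOBase, use_offsets: bool = True
) -> None:
    """Write the FPC-style sizes dialect read by :func:`read_sizes`."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        for fp in db:
            fh.write(f"{fp.clone_id}  {fp.n}\n")
            encoded = [
                b.size + (b.band_type - 1) * TYPE_OFFSET if use_offsets else b.size
                for b in fp.bands
            ]
            for i in range(0, len(encoded), 12):
                fh.write(" ".join(str(v) for v in encoded[i : i + 12]) + "\n")
            fh.write("-1\n")
    finally:
        if close:
            fh.close()


def read_band_tsv(path: str | Path, tolerance: int = 12) -> FingerprintDB:
    """Read the TSV alternative: columns clone_id, band_type, size."""
    bands: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "clone_id":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            bands.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    db = FingerprintDB(tolerance=tolerance)
    for clone_id, bb in bands.items():
        db.add(Fingerprint(clone_id, bb))
    return db


def write_band_tsv(db: FingerprintDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tband_type\tsize\n")
        for fp in db:
            for b in fp.bands:
                fh.write(f"{fp.clone_id}\t{b.band_type}\t{b.size}\n")


def read_markers(path: str | Path) -> dict[str, set[str]]:
    """Read marker anchors TSV: columns clone_id, marker_id."""
    anchors: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "clone_id":
                continue
            anchors.setdefault(parts[0], set()).add(parts[1])
    return anchors
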