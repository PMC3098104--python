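"""Clone-overlap significance metrics.

Three p-value metrics for the number of shared bands between two clones
with ``n1`` and ``n2`` bands:

``sulston``
    The classical binomial approximation used by FPC: with per-band match
    probability ``p1 = 1 - (1 - (2t+1)/G)**n2`` the upper binomial tail
    ``P(K >= k)`` is evaluated in log space.

``siid``
    Monte-Carlo calibrated tail for the same *iid* model of random clones.
    The complementary CDF of the shared-band count is simulated for a large
    number of random clone pairs and its deep tail approximated by
    ``exp{-(a0 + a1*k + a2*k**2)}``; below the fitted region the empirical
    tail is used directly.

``sind``
    Same construction but bands are *not* identically distributed: clones
    draw bands according to the estimated abundances ``f_b`` and the
    statistic is the weighted count ``k_w = -sum(ln f_b)`` over matched
    bands, so that rare shared bands contribute more evidence.

Shared genetic markers multiply any of the p-values by
``exp(-a_mark)`` per marker (default ``a_mark = 100 ln 10``, i.e. a factor
``10**-100``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from . import _kernels
from .fingerprints import (
    BandClassIndex,
    BandClassKeep,
    Fingerprint,
    FingerprintDB,
    shared_bands,
)

__all__ = [
    "MetricConfig",
    "TailModel",
    "OverlapRecord",
    "OverlapSet",
    "ModelCache",
    "IIDBandModel",
    "AbundanceBandModel",
    "sulston_score",
    "calibrate_tail",
    "p_value",
    "compute_overlaps",
]

LN10 = math.log(10.0)
METRICS = ("sulston", "siid", "sind")


@dataclass
class MetricConfig:
    """Parameters shared by the overlap metrics.

    tolerance
        Band-size tolerance ``t`` (in scored size units).
    universe
        Number ``G`` of distinct possible band values across all types.
    a_mark
        Natural-log weight of one shared marker (default ``100 ln 10``).
    pr0
        Significance cutoff ``Pr_0`` for declaring an overlap.
    reps
        Monte-Carlo pair count per tail calibration.
    seed
        Base seed for calibration randomness.
    prefilter_min_k
        Pairs sharing fewer bands are skipped entirely (no record stored).
    grid_step
        Band counts are rounded to this grid for tail-model caching.
    metrics
        Which metrics to evaluate; ``primary`` drives significance flags.
    """

    tolerance: int = 12
    universe: int = 18_000
    a_mark: float = 100.0 * LN10
    pr0: float = 1e-12
    reps: int = 100_000
    seed: int = 0
    prefilter_min_k: int = 5
    grid_step: int = 10
    metrics: tuple[str, ...] = ("sulston", "sind")
    primary: str = "sind"

    def __post_init__(self) -> None:
        if not 0 < self.pr0 < 1:
            raise ValueError("pr0 must be in (0, 1)")
        if self.a_mark <= 0:
            raise ValueError("a_mark must be positive")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.primary not in self.metrics:
            raise ValueError("primary metric must be among `metrics`")

    @property
    def effective_universe(self) -> int:
        """Distinct band values after collapsing the tolerance window."""
        return max(1, round(self.universe / (2 * self.tolerance + 1)))

    @property
    def log10_pr0(self) -> float:
        return math.log10(self.pr0)


# ---------------------------------------------------------------------------
# Sulston score


def sulston_score(n1: int, n2: int, k: int, tolerance: int, universe: int) -> float:
    """log10 of the classical Sulston overlap probability ``P(K >= k)``.

    Binomial upper tail with per-band match probability
    ``p1 = 1 - (1 - (2t+1)/G)**n2`` (``n1 <= n2``; arguments are swapped if
    needed), evaluated in log space so that extreme tails do not underflow.
    """
    if universe <= 0:
        raise ValueError("universe size G must be positive")
    if n1 > n2:
        n1, n2 = n2, n1
    if k > n1:
        raise ValueError(f"k={k} exceeds min(n1, n2)={n1}")
    if k <= 0:
        return 0.0
    w = (2 * tolerance + 1) / universe
    if w >= 1.0:
        return 0.0
    p1 = -math.expm1(n2 * math.log1p(-w))  # 1 - (1-w)^n2
    if p1 >= 1.0:
        return 0.0
    j = np.arange(k, n1 + 1)
    log_pmf = (
        gammaln(n1 + 1)
        - gammaln(j + 1)
        - gammaln(n1 - j + 1)
        + j * math.log(p1)
        + (n1 - j) * math.log1p(-p1)
    )
    return float(min(0.0, logsumexp(log_pmf) / LN10))


# ---------------------------------------------------------------------------
# Monte-Carlo calibrated tails


class IIDBandModel:
    """Random clones under the iid model: bands uniform over ``G_eff`` values.

    Duplicate draws collapse, matching is exact equality (the tolerance is
    folded into the effective universe size).  Statistic: shared count.
    """

    weighted = False

    def __init__(self, effective_universe: int) -> None:
        if effective_universe < 1:
            raise ValueError("effective universe must be >= 1")
        self.g = int(effective_universe)

    def simulate(self, reps: int, n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
        stats = np.empty(reps, dtype=np.int64)
        chunk = max(1, min(reps, int(4e6 / max(n1 + n2, 1))))
        done = 0
        while done < reps:
            c = min(chunk, reps - done)
            d1 = np.sort(rng.integers(0, self.g, size=(c, n1)), axis=1)
            d2 = np.sort(rng.integers(0, self.g, size=(c, n2)), axis=1)
            u1 = (np.diff(d1, axis=1) > 0).sum(axis=1) + 1
            u2 = (np.diff(d2, axis=1) > 0).sum(axis=1) + 1
            both = np.sort(np.concatenate([d1, d2], axis=1), axis=1)
            u12 = (np.diff(both, axis=1) > 0).sum(axis=1) + 1
            stats[done : done + c] = u1 + u2 - u12
            done += c
        return stats


class AbundanceBandModel:
    """Random clones drawing band classes proportionally to abundance ``f_b``.

    Statistic: ``k_w = sum(-ln f_b)`` over the shared classes.  Because an
    all-pairs run calibrates many band-count cells, the model keeps two
    master draw matrices (one per clone of a pair) and serves each cell
    from their column prefixes — the draws stay i.i.d. within every cell
    and deterministic under the model seed.
    """

    weighted = True

    def __init__(self, f: np.ndarray, seed: int = 0) -> None:
        f = np.asarray(f, dtype=float)
        if f.size == 0 or np.any(f <= 0) or np.any(f > 1):
            raise ValueError("abundances must lie in (0, 1]")
        self.f = f
        self.w = -np.log(f)
        p = f / f.sum()
        self.cum = np.cumsum(p)
        self.cum[-1] = 1.0
        self.seed = int(seed)
        self._pool: tuple[np.ndarray, np.ndarray] | None = None
        self._sorted: dict[tuple[int, int], np.ndarray] = {}

    def _masters(self, reps: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        if self._pool is not None and self._pool[0].shape[0] >= reps and self._pool[0].shape[1] >= n:
            return self._pool
        rng = np.random.default_rng(self.seed)
        dtype = np.uint16 if self.f.size < 2**16 else np.uint32
        shape = (reps, max(n, 8))
        d1 = np.searchsorted(self.cum, rng.random(shape), side="right").astype(dtype)
        d2 = np.searchsorted(self.cum, rng.random(shape), side="right").astype(dtype)
        self._pool = (d1, d2)
        self._sorted.clear()
        return self._pool

    def _sorted_prefix(self, side: int, reps: int, n: int) -> np.ndarray:
        """Row-sorted first-``n``-draws view of one master matrix (cached)."""
        key = (side, n)
        cached = self._sorted.get(key)
        if cached is not None and cached.shape[0] >= reps:
            return cached[:reps]
        master = self._masters(reps, n)[side]
        arr = np.sort(master[:reps, :n], axis=1)
        if len(self._sorted) >= 16:  # bound the cache footprint
            self._sorted.pop(next(iter(self._sorted)))
        self._sorted[key] = arr
        return arr

    def simulate(self, reps: int, n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
        a = self._sorted_prefix(0, reps, n1)
        b = self._sorted_prefix(1, reps, n2)
        return _kernels.sorted_intersect_weighted(a, b, self.w)


@dataclass
class TailModel:
    """Calibrated tail ``P(statistic >= x)`` for one band-count pair.

    Above ``k0`` the quadratic approximation
    ``exp{-(a0 + a1*x + a2*x**2)}`` is used; at or below ``k0`` the stored
    empirical tail table.  ``k0`` is the point beyond which the fitted tail
    stays under 1e-3.
    """

    n1: int
    n2: int
    a0: float
    a1: float
    a2: float
    k0: float
    values: np.ndarray  # ascending statistic values (empirical support)
    tails: np.ndarray  # P(S >= value), aligned with `values`
    reps: int
    seed: int
    weighted: bool
    x_max: float = math.inf  # largest simulated statistic (fit support end)

    def _quad(self, x: np.ndarray) -> np.ndarray:
        # quadratic inside the simulated support; linear continuation
        # beyond it (the true deep tail grows like k log k, so an
        # unbounded quadratic would overstate significance out there)
        xq = np.minimum(x, self.x_max)
        q = self.a0 + self.a1 * xq + self.a2 * xq * xq
        if self.a2 < 0:  # cap at the vertex to keep the tail non-increasing
            vx = -self.a1 / (2 * self.a2)
            q = np.minimum(q, self.a0 + self.a1 * vx + self.a2 * vx * vx)
        if math.isfinite(self.x_max):
            slope = max(self.a1 + 2 * self.a2 * self.x_max, 0.0)
            q = q + slope * np.maximum(x - self.x_max, 0.0)
        return q

    def log_tail(self, stat: float | np.ndarray) -> float | np.ndarray:
        """Natural-log tail probability, non-increasing in the statistic.

        Scalar in, scalar out; array in, array out.
        """
        scalar = np.ndim(stat) == 0
        x = np.atleast_1d(np.asarray(stat, dtype=float))
        out = np.empty_like(x)
        floor = math.log(0.5 / self.reps)
        emp = x <= self.k0
        if emp.any():
            idx = np.searchsorted(self.values, x[emp], side="left")
            vals = np.where(
                idx < self.values.size, np.log(self.tails[np.minimum(idx, self.tails.size - 1)]), floor
            )
            out[emp] = vals
        if (~emp).any():
            out[~emp] = -self._quad(x[~emp])
        out = np.minimum(out, 0.0)
        return float(out[0]) if scalar else out

    def log_tail_scalar(self, stat: float) -> float:
        return float(self.log_tail(float(stat)))


def _fit_quadratic(vals: np.ndarray, tails: np.ndarray, reps: int) -> tuple[float, float, float]:
    """Least-squares fit of ``-ln tail = a0 + a1 x + a2 x^2``.

    Support points are subsampled at log-spaced tail levels between
    ``10/reps`` and 0.5 so that the deep tail and the shoulder contribute
    evenly; observed statistics usually lie far beyond the simulable
    range, and a fit anchored only in a narrow deep-tail window
    extrapolates erratically there.  ``-ln tail`` of a shared-band count
    is convex, so a concave fit (a finite-sample artefact) degrades to
    the linear fit; fewer than 3 support points also degrade to linear,
    with a warning.
    """
    lo = max(10.0 / reps, 1.5 / reps)
    hi = 0.5
    levels = np.exp(np.linspace(math.log(lo), math.log(hi), 80))
    # smallest value whose tail is <= level (tails are non-increasing in vals)
    idx = tails.size - np.searchsorted(tails[::-1], levels, side="left")
    idx = np.unique(idx[(idx >= 0) & (idx < tails.size)])
    idx = idx[(tails[idx] >= lo) & (tails[idx] <= hi)]
    x = vals[idx].astype(float)
    yy = -np.log(tails[idx])
    if x.size >= 3:
        A = np.stack([np.ones_like(x), x, x * x], axis=1)
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        if coef[2] >= 0 and coef[1] + 2 * coef[2] * x[0] > 0:
            return float(coef[0]), float(coef[1]), float(coef[2])
        B = np.stack([np.ones_like(x), x], axis=1)
        lin, *_ = np.linalg.lstsq(B, yy, rcond=None)
        if lin[1] > 0:
            return float(lin[0]), float(lin[1]), 0.0
        return 0.0, float(yy[-1] / max(x[-1], 1e-12)), 0.0
    warnings.warn(
        "degenerate tail fit (<3 support points); falling back to linear",
        RuntimeWarning,
        stacklevel=3,
    )
    if x.size == 2:
        a1 = (yy[1] - yy[0]) / max(x[1] - x[0], 1e-12)
        return float(yy[0] - a1 * x[0]), float(a1), 0.0
    if x.size == 1 and x[0] > 0:
        return 0.0, float(yy[0] / x[0]), 0.0
    # no usable support: everything is in the bulk; steep linear fallback
    top = float(vals[-1]) if vals.size else 1.0
    return 0.0, math.log(max(reps, 2)) / max(top, 1.0), 0.0


def _solve_k0(a0: float, a1: float, a2: float) -> float:
    """Smallest x beyond which the fitted tail stays below 1e-3."""
    target = math.log(1000.0)
    if a2 > 0:
        disc = a1 * a1 - 4 * a2 * (a0 - target)
        root = (-a1 + math.sqrt(max(disc, 0.0))) / (2 * a2)
        vertex = -a1 / (2 * a2)
        return max(root, vertex, 0.0)
    if a2 == 0.0:
        if a1 <= 0:
            return math.inf
        return max((target - a0) / a1, 0.0)
    # a2 < 0: increasing branch only; the evaluation caps at the vertex
    vertex = -a1 / (2 * a2)
    peak = a0 + a1 * vertex + a2 * vertex * vertex
    if peak <= target:
        return math.inf
    disc = a1 * a1 - 4 * a2 * (a0 - target)
    root = (-a1 + math.sqrt(max(disc, 0.0))) / (2 * a2)  # smaller crossing
    return max(min(root, vertex), 0.0)


def calibrate_tail(
    n1: int,
    n2: int,
    band_model: IIDBandModel | AbundanceBandModel,
    reps: int = 100_000,
    seed: int = 0,
) -> TailModel:
    """Monte-Carlo calibration of the shared-band tail for ``(n1, n2)``.

    Simulates ``reps`` random clone pairs under ``band_model``, forms the
    empirical complementary CDF of the overlap statistic, and fits the
    quadratic deep-tail approximation.
    """
    if reps < 10_000:
        raise ValueError("reps must be >= 10000 for a usable tail")
    rng = np.random.default_rng(seed)
    stats = band_model.simulate(reps, n1, n2, rng)
    s = np.sort(stats)
    vals = np.unique(s)
    first = np.searchsorted(s, vals, side="left")
    tails = (reps - first) / reps
    a0, a1, a2 = _fit_quadratic(vals, tails, reps)
    k0 = _solve_k0(a0, a1, a2)
    # keep the empirical table compact: the quadratic serves beyond k0
    keep = tails >= 1e-4
    if keep.sum() > 4096:
        idx = np.linspace(0, keep.sum() - 1, 4096).astype(int)
        vals_k, tails_k = vals[keep][idx], tails[keep][idx]
    else:
        vals_k, tails_k = vals[keep], tails[keep]
    return TailModel(
        n1=n1,
        n2=n2,
        a0=a0,
        a1=a1,
        a2=a2,
        k0=k0,
        values=vals_k,
        tails=tails_k,
        reps=reps,
        seed=seed,
        weighted=band_model.weighted,
        x_max=float(vals[-1]),
    )


class ModelCache:
    """Lazily calibrated tail models on a grid of band-count pairs.

    Band counts are rounded to the nearest multiple of ``grid_step`` (at
    least one step) so an all-pairs run shares calibrations.
    """

    def __init__(self, cfg: MetricConfig, abundance: BandClassIndex | None = None) -> None:
        self.cfg = cfg
        self._models: dict[tuple[str, int, int], TailModel] = {}
        self._iid = IIDBandModel(cfg.effective_universe)
        self._abund = (
            AbundanceBandModel(abundance.f, seed=cfg.seed) if abundance is not None else None
        )

    def _round(self, n: int) -> int:
        step = self.cfg.grid_step
        return max(step, int(round(n / step)) * step)

    def cell(self, n1: int, n2: int) -> tuple[int, int]:
        a, b = sorted((self._round(n1), self._round(n2)))
        return a, b

    def get(self, metric: str, n1: int, n2: int) -> TailModel:
        a, b = self.cell(n1, n2)
        key = (metric, a, b)
        if key not in self._models:
            if metric == "siid":
                model = self._iid
            elif metric == "sind":
                if self._abund is None:
                    raise ValueError("sind metric requires estimated band abundances")
                model = self._abund
            else:
                raise ValueError(f"no tail model for metric {metric!r}")
            seed = (self.cfg.seed * 1_000_003 + 7_919 * a + 104_729 * b + hash(metric)) % (2**31)
            self._models[key] = calibrate_tail(a, b, model, reps=self.cfg.reps, seed=seed)
        return self._models[key]


# ---------------------------------------------------------------------------
# Overlap records


@dataclass
class OverlapRecord:
    """Shared-band statistics and p-values for one clone pair."""

    c1: str
    c2: str
    k_count: int
    k_weighted: float
    m: int
    log10p: dict[str, float] = field(default_factory=dict)
    significant: bool = False


class OverlapSet:
    """All evaluated pairwise overlaps, stored columnar for scale."""

    def __init__(
        self,
        clone_ids: Sequence[str],
        idx1: np.ndarray,
        idx2: np.ndarray,
        k_count: np.ndarray,
        k_weighted: np.ndarray,
        m: np.ndarray,
        log10p: dict[str, np.ndarray],
        significant: np.ndarray,
        cfg: MetricConfig,
    ) -> None:
        self.clone_ids = list(clone_ids)
        self._id_of = {c: i for i, c in enumerate(self.clone_ids)}
        self.idx1 = idx1
        self.idx2 = idx2
        self.k_count = k_count
        self.k_weighted = k_weighted
        self.m = m
        self.log10p = log10p
        self.significant = significant
        self.cfg = cfg
        self._row = {
            (int(a), int(b)): r for r, (a, b) in enumerate(zip(idx1.tolist(), idx2.tolist()))
        }

    def __len__(self) -> int:
        return self.idx1.size

    def row_of(self, c1: str, c2: str) -> int | None:
        try:
            a, b = self._id_of[c1], self._id_of[c2]
        except KeyError:
            return None
        if a > b:
            a, b = b, a
        return self._row.get((a, b))

    def get(self, c1: str, c2: str) -> OverlapRecord | None:
        r = self.row_of(c1, c2)
        if r is None:
            return None
        a, b = sorted((c1, c2))
        return OverlapRecord(
            c1=a,
            c2=b,
            k_count=int(self.k_count[r]),
            k_weighted=float(self.k_weighted[r]),
            m=int(self.m[r]),
            log10p={name: float(col[r]) for name, col in self.log10p.items()},
            significant=bool(self.significant[r]),
        )

    def weight(self, c1: str, c2: str, metric: str | None = None) -> float:
        """``W = -log10 Pr``; 0 for unevaluated/prefiltered pairs."""
        r = self.row_of(c1, c2)
        if r is None:
            return 0.0
        return -float(self.log10p[metric or self.cfg.primary][r])

    def iter_pairs(
        self, metric: str | None = None
    ) -> Iterator[tuple[str, str, float, bool]]:
        """Yield (c1, c2, W, significant) for all stored pairs."""
        metric = metric or self.cfg.primary
        col = self.log10p[metric]
        for r in range(len(self)):
            yield (
                self.clone_ids[self.idx1[r]],
                self.clone_ids[self.idx2[r]],
                -float(col[r]),
                bool(self.significant[r]),
            )

    def significant_pairs(
        self, pr0: float | None = None, metric: str | None = None
    ) -> list[tuple[str, str, float]]:
        """Pairs with ``Pr < pr0`` under ``metric`` (default: config values)."""
        metric = metric or self.cfg.primary
        cutoff = math.log10(pr0) if pr0 is not None else self.cfg.log10_pr0
        col = self.log10p[metric]
        rows = np.flatnonzero(col < cutoff)
        return [
            (
                self.clone_ids[self.idx1[r]],
                self.clone_ids[self.idx2[r]],
                -float(col[r]),
            )
            for r in rows
        ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "c1\tc2\tk_count\tk_weighted\tm\t"
                "log10p_sulston\tlog10p_siid\tlog10p_sind\tsignificant\n"
            )
            for r in range(len(self)):
                cols = []
                for name in METRICS:
                    cols.append(
                        f"{self.log10p[name][r]:.4f}" if name in self.log10p else "NA"
                    )
                fh.write(
                    f"{self.clone_ids[self.idx1[r]]}\t{self.clone_ids[self.idx2[r]]}\t"
                    f"{int(self.k_count[r])}\t{self.k_weighted[r]:.4f}\t{int(self.m[r])}\t"
                    f"{cols[0]}\t{cols[1]}\t{cols[2]}\t{int(self.significant[r])}\n"
                )


# ---------------------------------------------------------------------------
# Evaluation


def _marker_count(fp1: Fingerprint, fp2: Fingerprint) -> int:
    if not fp1.markers or not fp2.markers:
        return 0
    return len(fp1.markers & fp2.markers)


def p_value(
    fp1: Fingerprint,
    fp2: Fingerprint,
    metric: str,
    cfg: MetricConfig,
    models: ModelCache | None = None,
    abundance: BandClassIndex | None = None,
) -> OverlapRecord:
    """Overlap p-value for one clone pair under one metric.

    ``models`` must be supplied (or constructible from ``abundance``) for
    the Monte-Carlo metrics; the marker term is applied in log space for
    every metric.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "sind" and abundance is None:
        raise ValueError("sind requires estimated band abundances")
    k, pairs = shared_bands(fp1, fp2, cfg.tolerance)
    m = _marker_count(fp1, fp2)
    k_w = 0.0
    if abundance is not None and pairs:
        for b1, b2 in pairs:
            w1 = -math.log(float(abundance.f_of(b1.band_type, b1.size)))
            w2 = -math.log(float(abundance.f_of(b2.band_type, b2.size)))
            k_w += 0.5 * (w1 + w2)
    if metric == "sulston":
        ln_tail = sulston_score(fp1.n, fp2.n, k, cfg.tolerance, cfg.universe) * LN10
    else:
        if models is None:
            models = ModelCache(cfg, abundance)
        tm = models.get(metric, fp1.n, fp2.n)
        stat = k_w if metric == "sind" else float(k)
        ln_tail = tm.log_tail_scalar(stat)
    ln_p = ln_tail - cfg.a_mark * m
    a, b = sorted((fp1.clone_id, fp2.clone_id))
    rec = OverlapRecord(a, b, k, k_w, m, {metric: ln_p / LN10})
    rec.significant = rec.log10p[metric] < cfg.log10_pr0
    return rec


def _encode_db(
    db: FingerprintDB,
    clone_ids: Sequence[str],
    abundance: BandClassIndex | None,
    keep: BandClassKeep | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat encoded band arrays for the kernel: values, weights, offsets, n."""
    parts: list[np.ndarray] = []
    wparts: list[np.ndarray] = []
    offsets = np.zeros(len(clone_ids) + 1, dtype=np.int64)
    for i, cid in enumerate(clone_ids):
        fp = db[cid] if keep is None else db[cid].restricted(keep)
        encs = []
        ws = []
        for t in fp.band_types:
            sizes = fp.sizes_of_type(t)
            encs.append(t * _kernels.ENCODE_BASE + sizes)
            if abundance is not None:
                ws.append(-np.log(abundance.f_of(t, sizes)))
            else:
                ws.append(np.zeros(sizes.size))
        enc = np.concatenate(encs) if encs else np.empty(0, dtype=np.int64)
        w = np.concatenate(ws) if ws else np.empty(0)
        order = np.argsort(enc, kind="stable")
        parts.append(enc[order])
        wparts.append(w[order])
        offsets[i + 1] = offsets[i] + enc.size
    flat = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    weights = np.concatenate(wparts) if wparts else np.empty(0)
    n = np.diff(offsets)
    return flat, weights, offsets, n


def compute_overlaps(
    db: FingerprintDB,
    cfg: MetricConfig,
    clone_ids: Sequence[str] | None = None,
    models: ModelCache | None = None,
    keep: BandClassKeep | None = None,
) -> OverlapSet:
    """Evaluate all pairwise overlaps of the database (or a clone subset).

    Pairs sharing fewer than ``cfg.prefilter_min_k`` bands are skipped and
    produce no stored record; evaluated pairs are flagged significant when
    the primary metric beats ``cfg.pr0``.  ``keep`` restricts the band
    universe (jackknife replicates); tail models are shared through
    ``models`` and never recalibrated per replicate.
    """
    ids = sorted(clone_ids) if clone_ids is not None else sorted(db.clone_ids)
    need_abund = "sind" in cfg.metrics
    abundance = db.ensure_abundances() if need_abund else db.abundance
    if models is None:
        models = ModelCache(cfg, abundance)
    flat, weights, offsets, nbands = _encode_db(db, ids, abundance, keep)
    i1, i2, kc, kw = _kernels.pair_counts(
        flat, weights, offsets, len(ids), cfg.tolerance, max(cfg.prefilter_min_k, 1)
    )
    npairs = i1.size
    # shared markers: only pairs where both clones carry markers
    m = np.zeros(npairs, dtype=np.int32)
    has_m = np.array([bool(db[c].markers) for c in ids])
    if has_m.any() and npairs:
        cand = np.flatnonzero(has_m[i1] & has_m[i2])
        for r in cand.tolist():
            m[r] = _marker_count(db[ids[i1[r]]], db[ids[i2[r]]])
    log10p: dict[str, np.ndarray] = {}
    n1 = nbands[i1]
    n2 = nbands[i2]
    for metric in cfg.metrics:
        col = np.zeros(npairs)
        if metric == "sulston":
            for r in range(npairs):
                col[r] = sulston_score(
                    int(n1[r]), int(n2[r]), int(kc[r]), cfg.tolerance, cfg.universe
                )
        else:
            stat = kw if metric == "sind" else kc.astype(float)
            cells = np.stack(
                [np.minimum(n1, n2), np.maximum(n1, n2)], axis=1
            ) if npairs else np.empty((0, 2), dtype=int)
            # round to the model grid, then evaluate cell by cell
            step = cfg.grid_step
            cells = np.maximum(step, (np.round(cells / step) * step).astype(int))
            if npairs:
                uniq, inv = np.unique(cells, axis=0, return_inverse=True)
                for u, (a, b) in enumerate(uniq):
                    rows = np.flatnonzero(inv == u)
                    tm = models.get(metric, int(a), int(b))
                    col[rows] = tm.log_tail(stat[rows]) / LN10
        col -= (cfg.a_mark / LN10) * m
        log10p[metric] = np.minimum(col, 0.0)
    significant = (
        log10p[cfg.primary] < cfg.log10_pr0 if npairs else np.zeros(0, dtype=bool)
    )
    return OverlapSet(ids, i1, i2, kc, kw, m, log10p, significant, cfg)
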