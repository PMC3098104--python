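"""Tight inner loops for all-pairs fingerprint comparison.

Bands are encoded as ``band_type * ENCODE_BASE + size`` so that one sorted
int64 array per clone supports greedy tolerance matching across all types
with a single two-pointer sweep (types are separated by more than any
tolerance).  A numba-jitted kernel is used when numba is importable; a pure
Python fallback keeps small problems and exotic platforms working.
"""

from __future__ import annotations

import numpy as np

#: Must exceed the largest encodable band size plus any tolerance.
ENCODE_BASE = 1 << 21


def _pair_counts_py(flat, weights, offsets, n_clones, tolerance, min_k):
    out_i, out_j, out_k, out_w = [], [], [], []
    flat_l = flat.tolist()
    w_l = weights.tolist()
    offs = offsets.tolist()
    for a in range(n_clones):
        sa, ea = offs[a], offs[a + 1]
        for b in range(a + 1, n_clones):
            sb, eb = offs[b], offs[b + 1]
            i, j, k = sa, sb, 0
            kw = 0.0
            while i < ea and j < eb:
                d = flat_l[i] - flat_l[j]
                if d < -tolerance:
                    i += 1
                elif d > tolerance:
                    j += 1
                else:
                    k += 1
                    kw += 0.5 * (w_l[i] + w_l[j])
                    i += 1
                    j += 1
            if k >= min_k:
                out_i.append(a)
                out_j.append(b)
                out_k.append(k)
                out_w.append(kw)
    return (
        np.asarray(out_i, dtype=np.int32),
        np.asarray(out_j, dtype=np.int32),
        np.asarray(out_k, dtype=np.int32),
        np.asarray(out_w, dtype=np.float64),
    )


def _count_one_py(a, b, tolerance):
    i = j = k = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if d < -tolerance:
            i += 1
        elif d > tolerance:
            j += 1
        else:
            k += 1
            i += 1
            j += 1
    return k


try:  # pragma: no cover - exercised indirectly
    import numba as _nb

    @_nb.njit(cache=False)
    def _pair_counts_nb(flat, weights, offsets, n_clones, tolerance, min_k):
        cap = n_clones * (n_clones - 1) // 2
        oi = np.empty(cap, dtype=np.int32)
        oj = np.empty(cap, dtype=np.int32)
        ok = np.empty(cap, dtype=np.int32)
        ow = np.empty(cap, dtype=np.float64)
        m = 0
        for a in range(n_clones):
            sa, ea = offsets[a], offsets[a + 1]
            for b in range(a + 1, n_clones):
                sb, eb = offsets[b], offsets[b + 1]
                i, j, k = sa, sb, 0
                kw = 0.0
                while i < ea and j < eb:
                    d = flat[i] - flat[j]
                    if d < -tolerance:
                        i += 1
                    elif d > tolerance:
                        j += 1
                    else:
                        k += 1
                        kw += 0.5 * (weights[i] + weights[j])
                        i += 1
                        j += 1
                if k >= min_k:
                    oi[m] = a
                    oj[m] = b
                    ok[m] = k
                    ow[m] = kw
                    m += 1
        return oi[:m], oj[:m], ok[:m], ow[:m]

    @_nb.njit(cache=False)
    def _sorted_intersect_nb(a, b, w):
        out = np.empty(a.shape[0], dtype=np.float64)
        n1 = a.shape[1]
        n2 = b.shape[1]
        for r in range(a.shape[0]):
            i = 0
            j = 0
            s = 0.0
            while i < n1 and j < n2:
                va = a[r, i]
                vb = b[r, j]
                if va < vb:
                    i += 1
                elif vb < va:
                    j += 1
                else:
                    s += w[va]
                    while i < n1 and a[r, i] == va:
                        i += 1
                    while j < n2 and b[r, j] == vb:
                        j += 1
            out[r] = s
        return out

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _sorted_intersect_py(a, b, w):
    out = np.empty(a.shape[0], dtype=np.float64)
    for r in range(a.shape[0]):
        ar = a[r]
        br = b[r]
        i = j = 0
        n1, n2 = ar.size, br.size
        s = 0.0
        while i < n1 and j < n2:
            va, vb = ar[i], br[j]
            if va < vb:
                i += 1
            elif vb < va:
                j += 1
            else:
                s += w[va]
                while i < n1 and ar[i] == va:
                    i += 1
                while j < n2 and br[j] == vb:
                    j += 1
        out[r] = s
    return out


def sorted_intersect_weighted(a, b, w):
    """Row-wise weighted set intersection of two row-sorted id matrices.

    Duplicate ids within a row count once; ``w`` maps id -> weight.
    """
    w = np.ascontiguousarray(w, dtype=np.float64)
    if HAVE_NUMBA:
        return _sorted_intersect_nb(
            np.ascontiguousarray(a), np.ascontiguousarray(b), w
        )
    return _sorted_intersect_py(a, b, w)


def pair_counts(flat, weights, offsets, n_clones, tolerance, min_k):
    """Greedy shared-band count and weighted sum for every clone pair.

    Returns (i, j, k, k_weighted) arrays for pairs with k >= min_k.
    """
    flat = np.ascontiguousarray(flat, dtype=np.int64)
    weights = np.ascontiguousarray(weights, dtype=np.float64)
    offsets = np.ascontiguousarray(offsets, dtype=np.int64)
    if HAVE_NUMBA and n_clones >= 40:
        return _pair_counts_nb(flat, weights, offsets, n_clones, int(tolerance), int(min_k))
    return _pair_counts_py(flat, weights, offsets, n_clones, int(tolerance), int(min_k))
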