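"""Fingerprint model: sizes-file dialect, tolerance matching, abundances,
buried-clone detection."""

import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lincontig as lc
from lincontig.fingerprints import (
    estimate_abundances,
    find_buried,
    read_sizes,
    shared_band_count,
    shared_bands,
    write_sizes,
)


class TestSizesFile:
    def test_offset_decoding(self, tmp_path):
        p = tmp_path / "toy.sizes"
        p.write_text("cA  3\n120 180 5120\n-1\n")
        db = read_sizes(p, k_types=4, tolerance=4)
        fp = db["cA"]
        assert [(b.band_type, b.size) for b in fp.bands] == [(1, 120), (1, 180), (2, 120)]

    def test_empty_file_gives_empty_db(self, tmp_path):
        p = tmp_path / "empty.sizes"
        p.write_text("")
        assert read_sizes(p).clone_count == 0

    @pytest.mark.parametrize(
        "text, message",
        [
            ("cA 4\n120 180 5120\n-1\n", "declared 4"),
            ("cA 1\n120\n-1\ncA 1\n130\n-1\n", "duplicate"),
            ("cA 1\n-7\n-1\n", "size"),
            ("cA 2\n120 130\n", "terminated"),
        ],
    )
    def test_malformed_records_are_hard_errors(self, tmp_path, text, message):
        p = tmp_path / "bad.sizes"
        p.write_text(text)
        with pytest.raises(ValueError, match=message):
            read_sizes(p)

    def test_round_trip_identity(self, tmp_path):
        # offsets disambiguate the type only while sizes stay below the
        # 5000 offset, so the round-trip law is stated on that domain
        rng = np.random.default_rng(31)
        clones = [
            lc.Fingerprint(
                f"c{i:02d}",
                [
                    (int(t), int(s))
                    for t, s in zip(rng.integers(1, 5, 40), rng.integers(1, 5000, 40))
                ],
            )
            for i in range(12)
        ]
        db = lc.FingerprintDB(clones, tolerance=4)
        p = tmp_path / "rt.sizes"
        write_sizes(db, p)
        back = read_sizes(p, tolerance=db.tolerance)
        assert back.clone_ids == db.clone_ids
        for cid in db.clone_ids:
            assert [(b.band_type, b.size) for b in back[cid].bands] == [
                (b.band_type, b.size) for b in db[cid].bands
            ]

    def test_simulated_sizes_file_reread_preserves_matching(self, small_library, tmp_path):
        # FPC-style files carry the raw offset-encoded values; re-reading
        # them as untyped bands preserves tolerance matching because the
        # type offsets keep band types (approximately) apart
        paths = lc.write_fpc(small_library, tmp_path)
        flat = read_sizes(paths["sizes"], use_offsets=False, tolerance=small_library.config.tolerance)
        db = small_library.to_db()
        ids = db.clone_ids[:10]
        for a in ids[:5]:
            for b in ids[5:]:
                k_typed = shared_band_count(db[a], db[b], db.tolerance)
                k_flat = shared_band_count(flat[a], flat[b], db.tolerance)
                assert abs(k_typed - k_flat) <= 2


bands_strategy = st.lists(
    st.tuples(st.integers(1, 3), st.integers(1, 200)), min_size=1, max_size=40
)


class TestSharedBands:
    def test_type_mismatch_never_matches(self):
        f1 = lc.Fingerprint("x", [(1, 100)])
        f2 = lc.Fingerprint("y", [(2, 100)])
        assert shared_bands(f1, f2, 4)[0] == 0

    def test_tolerance_window(self):
        f1 = lc.Fingerprint("x", [(1, 100)])
        f2 = lc.Fingerprint("y", [(1, 103)])
        assert shared_bands(f1, f2, 4)[0] == 1
        assert shared_bands(f1, f2, 2)[0] == 0

    @settings(max_examples=50, deadline=None)
    @given(bands_strategy, bands_strategy, st.integers(0, 5))
    def test_symmetry(self, b1, b2, t):
        f1, f2 = lc.Fingerprint("x", b1), lc.Fingerprint("y", b2)
        assert shared_bands(f1, f2, t)[0] == shared_bands(f2, f1, t)[0]
        assert shared_band_count(f1, f2, t) == shared_bands(f1, f2, t)[0]

    @settings(max_examples=30, deadline=None)
    @given(bands_strategy)
    def test_self_overlap_equals_band_count(self, b1):
        f = lc.Fingerprint("x", b1)
        assert shared_bands(f, f, 0)[0] == f.n

    def test_zero_tolerance_equals_multiset_intersection(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            s1 = rng.integers(1, 200, size=50)
            s2 = rng.integers(1, 200, size=50)
            f1 = lc.Fingerprint("x", [(1, int(v)) for v in s1])
            f2 = lc.Fingerprint("y", [(1, int(v)) for v in s2])
            oracle = sum((Counter(s1.tolist()) & Counter(s2.tolist())).values())
            assert shared_bands(f1, f2, 0)[0] == oracle


class TestAbundances:
    def test_odds_formula(self):
        # 100 clones, 100 bands each; one band class in half the clones
        clones = []
        for i in range(100):
            sizes = [(1, 1000 + 10 * j) for j in range(99)]
            sizes.append((2, 500) if i < 50 else (2, 900))
            clones.append(lc.Fingerprint(f"c{i:03d}", sizes))
        db = lc.FingerprintDB(clones, tolerance=0)
        idx = estimate_abundances(db)
        f_half = idx.f_of(2, 500)
        assert f_half == pytest.approx((0.5 / 0.5) / 100.0, rel=1e-9)

    def test_ubiquitous_band_capped(self):
        clones = [lc.Fingerprint(f"c{i}", [(1, 100), (1, 200 + i)]) for i in range(5)]
        db = lc.FingerprintDB(clones, tolerance=0)
        idx = estimate_abundances(db)
        assert idx.f_of(1, 100) == 1.0

    def test_recovers_known_generative_abundance(self):
        # clones are n i.i.d. band draws where class b has per-draw
        # probability f_b (so pi_b = 1 - (1 - f_b)^n); the odds estimator
        # must recover f_b within 3 standard errors for well-covered bands
        # validity regime of the odds approximation: f_b << 1/n
        rng = np.random.default_rng(5)
        n_classes, n_clones, n_draws = 3000, 2000, 100
        f_true = np.concatenate(
            [np.full(n_classes // 2, 0.5), np.full(n_classes // 2, 1.5)]
        ) / n_classes
        f_true /= f_true.sum()
        clones = []
        cum = np.cumsum(f_true)
        for i in range(n_clones):
            draws = np.searchsorted(cum, rng.random(n_draws))
            clones.append(
                lc.Fingerprint(
                    f"c{i:04d}", [(1, 10 * (int(b) + 1)) for b in np.unique(draws)]
                )
            )
        db = lc.FingerprintDB(clones, tolerance=0)
        idx = estimate_abundances(db)
        n_mean = db.n_mean
        checked = 0
        for cls in range(0, n_classes, 13):
            size = 10 * (cls + 1)
            pi = float(idx.pi[idx.class_of(1, size)])
            if pi * n_clones < 20:
                continue
            est = float(idx.f_of(1, size))
            # binomial error on pi propagated through the odds formula
            se = np.sqrt(pi * (1 - pi) / n_clones) / ((1 - pi) ** 2) / n_mean
            # 3 sampling SEs plus the O(n f) small-f approximation bias
            assert abs(est - f_true[cls]) < 3 * se + n_draws * f_true[cls] ** 2
            checked += 1
        assert checked >= 10

    def test_every_observed_band_has_abundance(self, small_db):
        idx = small_db.ensure_abundances()
        for fp in small_db:
            for b in fp.bands:
                f = float(idx.f_of(b.band_type, b.size))
                assert 0 < f <= 1


class TestBuried:
    def test_exact_containment(self):
        host = lc.Fingerprint("host", [(1, s) for s in range(100, 200, 2)])
        sub = lc.Fingerprint("sub", [(1, s) for s in range(120, 180, 2)])
        db = lc.FingerprintDB([host, sub], tolerance=0)
        assert find_buried(db, q=0.9) == [("sub", "host")]

    def test_disjoint_clones_not_buried(self):
        a = lc.Fingerprint("a", [(1, 100), (1, 110)])
        b = lc.Fingerprint("b", [(1, 300), (1, 310), (1, 320)])
        db = lc.FingerprintDB([a, b], tolerance=0)
        assert find_buried(db, q=0.5) == []

    def test_simulated_nested_clones_detected(self):
        # nested sub-interval clones with 5% missing bands, no size noise
        rng = np.random.default_rng(9)
        hosts, buried_truth, clones = [], [], []
        for i in range(30):
            base = 1000 * (i + 1)
            sizes = [base + 3 * j for j in range(120)]
            hosts.append(f"h{i:02d}")
            clones.append(lc.Fingerprint(f"h{i:02d}", [(1, s) for s in sizes]))
            keep = [s for s in sizes[20:100] if rng.random() > 0.05]
            buried_truth.append((f"s{i:02d}", f"h{i:02d}"))
            clones.append(lc.Fingerprint(f"s{i:02d}", [(1, s) for s in keep]))
        db = lc.FingerprintDB(clones, tolerance=0)
        found = dict(find_buried(db, q=0.9))
        hits = sum(found.get(s) == h for s, h in buried_truth)
        assert hits >= 0.95 * len(buried_truth)
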