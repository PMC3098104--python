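"""Overlap metrics: Sulston score, Monte-Carlo tail calibration, marker
term, prefilter soundness — each checked against an independent oracle."""

import math
from functools import lru_cache

import numpy as np
import pytest
from scipy.stats import hypergeom, spearmanr

import lincontig as lc
from lincontig.metrics import (
    AbundanceBandModel,
    IIDBandModel,
    MetricConfig,
    ModelCache,
    calibrate_tail,
    compute_overlaps,
    p_value,
    sulston_score,
)

LN10 = math.log(10)


# ---------------------------------------------------------------------------
# exact oracle for the iid model: clones are n uniform draws from G values
# with duplicates collapsed; the set size follows the occupancy (Stirling)
# distribution and the intersection given the sizes is hypergeometric


@lru_cache(maxsize=None)
def _stirling2(n: int, k: int) -> int:
    if n == k:
        return 1
    if k == 0 or k > n:
        return 0
    return k * _stirling2(n - 1, k) + _stirling2(n - 1, k - 1)


def exact_iid_tail(G: int, n1: int, n2: int, k: int) -> float:
    def size_dist(n):
        probs = {}
        for s in range(1, n + 1):
            c = math.comb(G, s) * _stirling2(n, s) * math.factorial(s)
            probs[s] = c / G**n
        return probs

    p1, p2 = size_dist(n1), size_dist(n2)
    total = 0.0
    for s1, q1 in p1.items():
        for s2, q2 in p2.items():
            total += q1 * q2 * float(hypergeom.sf(k - 1, G, s1, s2))
    return total


class TestSulston:
    def test_zero_shared_bands_gives_p_one(self):
        assert sulston_score(10, 20, 0, 4, 18000) == 0.0

    def test_single_bernoulli(self):
        # n1 = n2 = 1, (2t+1)/G = 0.1 -> P(K >= 1) = 0.1
        assert sulston_score(1, 1, 1, 0, 10) == pytest.approx(-1.0, abs=1e-12)

    def test_k_exceeding_min_band_count_is_error(self):
        with pytest.raises(ValueError):
            sulston_score(3, 10, 4, 0, 100)

    def test_against_brute_force_enumeration(self):
        # random clone pairs with n distinct bands each (the score's own
        # sampling frame), >= 1e6 draws; the binomial approximation must
        # track the simulated tail within 10% where k stays small
        # relative to n (its stated validity domain)
        from lincontig._kernels import sorted_intersect_weighted
        from scipy.stats import hypergeom

        G, t, n1, n2 = 300, 0, 10, 20
        rng = np.random.default_rng(123)
        reps = 1_000_000
        k_obs = np.empty(reps, dtype=np.float64)
        chunk = 20_000
        for s in range(0, reps, chunk):
            d1 = np.sort(np.argsort(rng.random((chunk, G)), axis=1)[:, :n1], axis=1)
            d2 = np.sort(np.argsort(rng.random((chunk, G)), axis=1)[:, :n2], axis=1)
            k_obs[s : s + chunk] = sorted_intersect_weighted(d1, d2, np.ones(G))
        for k in (1, 2, 3):
            mc = float((k_obs >= k).mean())
            exact = float(hypergeom.sf(k - 1, G, n1, n2))
            se = math.sqrt(exact * (1 - exact) / reps)
            assert abs(mc - exact) < 4 * se  # the enumeration itself is sound
            apx = 10.0 ** sulston_score(n1, n2, k, t, G)
            assert apx == pytest.approx(mc, rel=0.10)

    def test_monotone_in_k(self):
        vals = [sulston_score(30, 40, k, 4, 18000) for k in range(31)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCalibratedTails:
    def test_fitted_tail_non_increasing(self):
        model = IIDBandModel(50)
        tm = calibrate_tail(8, 8, model, reps=20_000, seed=2)
        xs = np.arange(0, 9, dtype=float)
        lt = tm.log_tail(xs)
        assert np.all(np.diff(lt) <= 1e-12)
        assert np.all(lt <= 0)

    def test_empirical_passthrough_below_threshold(self):
        model = IIDBandModel(50)
        tm = calibrate_tail(8, 8, model, reps=20_000, seed=2)
        # the bulk (tail ~ 0.5) must be served by the empirical table
        med = np.median(tm.values)
        assert med <= tm.k0
        lt = float(tm.log_tail(med))
        assert math.exp(lt) == pytest.approx(
            float(tm.tails[np.searchsorted(tm.values, med)]), rel=1e-6
        )

    def test_tail_matches_exact_enumeration_small_universe(self):
        G, n = 20, 5
        model = IIDBandModel(G)
        reps = 100_000
        tm = calibrate_tail(n, n, model, reps=reps, seed=7)
        for k in (2, 3, 4):
            exact = exact_iid_tail(G, n, n, k)
            approx = math.exp(float(tm.log_tail(float(k))))
            se = math.sqrt(exact * (1 - exact) / reps)
            # within 3 Monte-Carlo standard errors or a factor of 2
            assert abs(approx - exact) < max(3 * se, exact)

    def test_weighted_model_reduces_to_count_under_uniform_abundance(self):
        f = np.full(60, 0.05)
        model = AbundanceBandModel(f, seed=3)
        stats = model.simulate(5000, 10, 10, np.random.default_rng(0))
        w = -math.log(0.05)
        ks = stats / w
        assert np.allclose(ks, np.round(ks))


class TestPValue:
    def _cfg(self, **kw):
        defaults = dict(
            tolerance=0, universe=500, reps=20_000, seed=5, metrics=("sulston", "siid"),
            primary="siid", prefilter_min_k=1,
        )
        defaults.update(kw)
        return MetricConfig(**defaults)

    def test_no_overlap_no_marker_gives_p_one(self):
        cfg = self._cfg()
        f1 = lc.Fingerprint("a", [(1, 10)])
        f2 = lc.Fingerprint("b", [(1, 400)])
        rec = p_value(f1, f2, "sulston", cfg)
        assert rec.log10p["sulston"] == 0.0

    def test_marker_term_multiplies_by_1e_minus_100(self):
        cfg = self._cfg()
        f1 = lc.Fingerprint("a", [(1, 10)], markers=["m1"])
        f2 = lc.Fingerprint("b", [(1, 400)], markers=["m1"])
        base = p_value(
            lc.Fingerprint("a", [(1, 10)]), lc.Fingerprint("b", [(1, 400)]), "sulston", cfg
        )
        rec = p_value(f1, f2, "sulston", cfg)
        assert rec.m == 1
        assert rec.log10p["sulston"] == pytest.approx(base.log10p["sulston"] - 100.0)

    def test_monotone_in_k_and_symmetric(self):
        cfg = self._cfg()
        models = ModelCache(cfg)
        prev = 1.0
        for k in range(0, 9):
            f1 = lc.Fingerprint("a", [(1, 10 * i) for i in range(1, 9)])
            shared = [(1, 10 * i) for i in range(1, k + 1)]
            rest = [(1, 300 + 10 * i) for i in range(8 - k)]
            f2 = lc.Fingerprint("b", shared + rest)
            r12 = p_value(f1, f2, "siid", cfg, models=models)
            r21 = p_value(f2, f1, "siid", cfg, models=models)
            assert r12.log10p["siid"] == r21.log10p["siid"]
            assert r12.log10p["siid"] <= prev + 1e-9
            prev = r12.log10p["siid"]

    def test_uniform_abundance_sind_ranks_equal_siid_ranks(self):
        rng = np.random.default_rng(17)
        clones = [
            lc.Fingerprint(f"c{i:02d}", [(1, 10 * int(v) + 10) for v in rng.integers(0, 300, 30)])
            for i in range(50)
        ]
        db = lc.FingerprintDB(clones, tolerance=0)
        idx = db.ensure_abundances()
        idx.f[:] = 0.01  # exactly uniform abundances
        cfg = MetricConfig(
            tolerance=0, universe=3000, reps=20_000, seed=2,
            metrics=("siid", "sind"), primary="sind", prefilter_min_k=1,
        )
        ov = compute_overlaps(db, cfg)
        assert len(ov) >= 100
        rho = spearmanr(ov.log10p["siid"], ov.log10p["sind"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-9)


class TestComputeOverlaps:
    def test_two_identical_clones(self):
        f = [(1, 10 * i) for i in range(1, 31)]
        db = lc.FingerprintDB(
            [lc.Fingerprint("a", f), lc.Fingerprint("b", f)], tolerance=0
        )
        cfg = MetricConfig(
            tolerance=0, universe=1000, reps=20_000, seed=1,
            metrics=("sulston",), primary="sulston", prefilter_min_k=1,
        )
        ov = compute_overlaps(db, cfg)
        assert len(ov) == 1
        assert ov.get("a", "b").k_count == 30

    def test_prefilter_skips_pairs_without_records(self, toy_db):
        cfg = MetricConfig(
            tolerance=0, universe=200, reps=20_000, seed=1,
            metrics=("sulston",), primary="sulston", prefilter_min_k=1,
        )
        ov = compute_overlaps(toy_db, cfg)
        assert ov.get("a", "e") is None  # zero shared bands -> no record
        assert ov.weight("a", "e") == 0.0

    def test_prefilter_soundness_on_simulated_library(self, noisy_db):
        """The significant-pair set is unchanged by the k-prefilter."""
        opts = lc.PipelineOptions(calibration_reps=20_000, seed=4)
        from lincontig.pipeline import default_metric_config

        cfg5 = default_metric_config(noisy_db, opts)
        ov5 = compute_overlaps(noisy_db, cfg5)
        cfg1 = MetricConfig(**{**cfg5.__dict__, "prefilter_min_k": 1})
        ov1 = compute_overlaps(noisy_db, cfg1)
        sig5 = {(a, b) for a, b, _ in ov5.significant_pairs()}
        sig1 = {(a, b) for a, b, _ in ov1.significant_pairs()}
        assert sig5 == sig1
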