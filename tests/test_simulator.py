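"""Library simulator: site finding, clone sampling, band generation rules,
observation noise, the tolerance-match formula, summaries and FPC output."""

import math
import re

import numpy as np
import pytest

import lincontig as lc
from lincontig.fingerprints import read_sizes
from lincontig.simulator import (
    SimConfig,
    boundary_index,
    encode_band,
    find_sites,
    fingerprint_true,
    observe,
    random_genome,
    simulate_clones,
    summarize,
    tolerance_match_prob,
    write_fpc,
)


class TestGenome:
    def test_length_and_determinism(self):
        s1 = random_genome(10_000, seed=4)
        s2 = random_genome(10_000, seed=4)
        assert len(s1) == 10_000
        assert s1 == s2
        assert random_genome(1000, seed=5) != random_genome(1000, seed=6)

    def test_gc_content_within_binomial_bound(self):
        n = 200_000
        s = random_genome(n, seed=1, gc=0.44)
        gc = (s.count("G") + s.count("C")) / n
        assert abs(gc - 0.44) < 3 * math.sqrt(0.44 * 0.56 / n)


class TestSites:
    def test_overlapping_motifs_found(self):
        assert find_sites("AAGCTTAAGCTT", "AAGCTT").tolist() == [0, 6]
        # overlapping occurrences
        assert find_sites("GGGG", "GG").tolist() == [0, 1, 2]

    def test_absent_motif_leaves_sentinels_only(self):
        r = boundary_index("ACGTACGT", "AAGCTT")
        assert r.tolist() == [0, 8]

    def test_counts_match_naive_scan_oracle(self):
        s = random_genome(50_000, seed=8)
        for motif in ("GGATCC", "GGCC", "AAGCTT"):
            naive = sum(
                1 for i in range(len(s) - len(motif) + 1) if s[i : i + len(motif)] == motif
            )
            assert find_sites(s, motif).size == naive


class TestBandRules:
    def _sites(self):
        return {
            "BamHI": np.array([100, 300]),
            "EcoRI": np.array([500]),
            "XbaI": np.array([], dtype=np.int64),
            "XhoI": np.array([], dtype=np.int64),
            "blunt": np.array([260, 340]),
        }

    def test_fragment_between_two_different_enzymes_counted_twice(self):
        cfg = SimConfig()
        sites = {
            "BamHI": np.array([100]),
            "EcoRI": np.array([300]),
            "XbaI": np.array([], dtype=np.int64),
            "XhoI": np.array([], dtype=np.int64),
            "blunt": np.array([], dtype=np.int64),
        }
        bands = fingerprint_true([(0, 1000, 1)], sites, cfg)
        # fragment [100, 300) of length 200 bounded by BamHI and EcoRI
        assert (1, 200) in bands and (2, 200) in bands

    def test_blunt_bounded_fragment_yields_no_band(self):
        cfg = SimConfig()
        sites = {
            "BamHI": np.array([], dtype=np.int64),
            "EcoRI": np.array([], dtype=np.int64),
            "XbaI": np.array([], dtype=np.int64),
            "XhoI": np.array([], dtype=np.int64),
            "blunt": np.array([100, 300]),
        }
        assert fingerprint_true([(0, 1000, 1)], sites, cfg) == []

    def test_band_length_window_filters(self):
        cfg = SimConfig()
        sites = {
            "BamHI": np.array([100, 140, 800]),  # 40 bp: below window
            "EcoRI": np.array([], dtype=np.int64),
            "XbaI": np.array([], dtype=np.int64),
            "XhoI": np.array([], dtype=np.int64),
            "blunt": np.array([], dtype=np.int64),
        }
        bands = fingerprint_true([(0, 1000, 1)], sites, cfg)
        assert (1, 40) not in bands  # below the window
        assert (1, 660) not in bands  # above the window
        assert (1, 100) in bands  # clone start to first BamHI site

    def test_double_count_conservation(self):
        """Total bands before the window equals, per fragment, the number
        of distinct protruding-end enzymes bounding it."""
        cfg = SimConfig(band_min=1, band_max=10**9)
        sites = self._sites()
        bands = fingerprint_true([(0, 1000, 1)], sites, cfg)
        # cut positions: 0,100,260,300,340,500,1000
        # fragments and their protruding bounds:
        # [0,100) Bam -> 1; [100,260) Bam -> 1; [260,300) Bam -> 1;
        # [300,340) Bam -> 1; [340,500) Eco -> 1; [500,1000) Eco -> 1
        assert len(bands) == 6


class TestObserve:
    def test_offset_encoding_example(self):
        # 200 bp band of type 3 at zero error: 200*30 + 2*5000 = 16000
        assert encode_band(3, 200 * 30) == 16000

    def test_no_noise_observation_is_exact_scaling(self):
        cfg = SimConfig(eps=1e-12, p_missing=0.0, n_min=1)
        rng = np.random.default_rng(0)
        fp, reason = observe([(2, 200), (1, 100)], cfg, rng, "x")
        assert reason is None
        assert [(b.band_type, b.size) for b in fp.bands] == [(1, 3000), (2, 6000)]

    def test_band_count_filter_drops_clone(self):
        cfg = SimConfig()
        rng = np.random.default_rng(0)
        fp, reason = observe([(1, 100)] * 10, cfg, rng, "x")
        assert fp is None and "too-few" in reason

    def test_retained_band_fraction_matches_p_missing(self):
        cfg = SimConfig(n_min=1, n_max=10**9)
        rng = np.random.default_rng(3)
        total = kept = 0
        for _ in range(200):
            fp, _ = observe([(1, 100 + i) for i in range(100)], cfg, rng, "x")
            total += 100
            kept += fp.n
        frac = kept / total
        assert abs(frac - 0.95) < 3 * math.sqrt(0.95 * 0.05 / total)


class TestToleranceMatchProb:
    def test_printed_value(self):
        assert round(tolerance_match_prob(0.2, 0.4, 0.9), 2) == 0.94

    def test_limits(self):
        assert tolerance_match_prob(0.2, 1e-9, 0.9) == pytest.approx(0.0, abs=1e-6)
        assert tolerance_match_prob(0.2, 0.4, 1.0) == pytest.approx(1.0)

    def test_outside_validity_range_is_error(self):
        with pytest.raises(ValueError):
            tolerance_match_prob(0.2, 0.5, 0.9)

    def test_monte_carlo_cross_check(self):
        """Closed form vs direct simulation of band-pair observations."""
        eps, t, p_eps = 0.2, 0.4, 0.9
        rng = np.random.default_rng(12)
        n = 400_000
        def errs():
            wide = rng.random(n) >= p_eps
            e = rng.uniform(-eps, eps, n)
            e[wide] = rng.uniform(-3 * eps, 3 * eps, n)[wide]
            return e
        diff = np.abs(errs() - errs())
        mc = float((diff < t).mean())
        tau = tolerance_match_prob(eps, t, p_eps)
        assert abs(mc - tau) < 3 * math.sqrt(tau * (1 - tau) / n)


class TestLibrary:
    def test_determinism_under_fixed_seed(self):
        seq = random_genome(300_000, seed=2)
        cfg = SimConfig(n_clones=30, seed=9)
        a = simulate_clones(seq, cfg)
        b = simulate_clones(seq, cfg)
        for ca, cb in zip(a.clones, b.clones):
            assert ca.parts == cb.parts
            assert ca.true_bands == cb.true_bands
            if ca.observed is not None:
                assert [x.size for x in ca.observed.bands] == [
                    x.size for x in cb.observed.bands
                ]

    def test_chimera_fraction_matches_parameter(self):
        seq = random_genome(2_000_000, seed=3)
        cfg = SimConfig(n_clones=600, p_chimer=0.2, seed=5)
        lib = simulate_clones(seq, cfg)
        frac = sum(c.chimeric for c in lib.clones) / len(lib.clones)
        assert abs(frac - 0.2) < 3 * math.sqrt(0.2 * 0.8 / 600)

    def test_summary_identities(self, small_library):
        s = summarize(small_library)
        lib = small_library
        assert s["n_clones_simulated"] == len(lib.clones)
        assert s["n_clones_retained"] == len(lib.retained)
        cov = sum(c.length for c in lib.clones) / lib.length
        assert s["coverage"] == pytest.approx(cov)
        assert s["tolerance"] == lib.config.tolerance

    def test_empty_library_summary_is_zeros(self):
        lib = lc.SimLibrary("g", 1000, np.array([0, 1000]), {}, [], SimConfig())
        s = summarize(lib)
        assert s["n_clones_simulated"] == 0
        assert s["coverage"] == 0


class TestWriteFpc:
    def test_round_trip_and_ground_truth(self, small_library, tmp_path):
        paths = write_fpc(small_library, tmp_path)
        db = read_sizes(
            paths["sizes"], k_types=4, tolerance=small_library.config.tolerance,
            use_offsets=False,
        )
        assert db.clone_count == len(small_library.retained)
        gt = paths["ground_truth"].read_text().strip().splitlines()
        assert len(gt) - 1 == len(small_library.clones)  # header + all clones
        dropped = [l for l in gt[1:] if l.split("\t")[1] == "0"]
        assert all("-" != l.split("\t")[2] for l in dropped)

    def test_true_partition_file_lists_retained_clones(self, small_library, tmp_path):
        paths = write_fpc(small_library, tmp_path)
        rows = paths["true_partition"].read_text().strip().splitlines()[1:]
        assert len(rows) == len(small_library.retained)
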