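"""Shared fixtures: small synthetic libraries and their overlap sets."""

from __future__ import annotations

import numpy as np
import pytest

import lincontig as lc
from lincontig.pipeline import PipelineOptions, default_metric_config


@pytest.fixture(scope="session")
def small_library():
    """Noise-free 1 Mbp library: ~100 clones, no chimeras, no missing bands."""
    seq = lc.random_genome(1_000_000, seed=3)
    cfg = lc.SimConfig(n_clones=100, p_chimer=0.0, p_missing=0.0, eps=1e-9, seed=3)
    return lc.simulate_clones(seq, cfg)


@pytest.fixture(scope="session")
def small_db(small_library):
    return small_library.to_db()


@pytest.fixture(scope="session")
def small_overlaps(small_db):
    opts = PipelineOptions(calibration_reps=20_000, seed=1)
    cfg = default_metric_config(small_db, opts)
    return lc.compute_overlaps(small_db, cfg)


@pytest.fixture(scope="session")
def noisy_library():
    """2 Mbp library with the default noise model and chimeras."""
    seq = lc.random_genome(2_000_000, seed=11)
    cfg = lc.SimConfig(n_clones=200, seed=11)
    return lc.simulate_clones(seq, cfg)


@pytest.fixture(scope="session")
def noisy_db(noisy_library):
    return noisy_library.to_db()


def toy_fingerprints():
    """Four clones on a deterministic chain a-b-c-d plus a singleton."""
    mk = lambda cid, sizes: lc.Fingerprint(cid, [(1, s) for s in sizes])
    a = mk("a", range(100, 160, 2))
    b = mk("b", range(130, 190, 2))
    c = mk("c", range(160, 220, 2))
    d = mk("d", range(190, 250, 2))
    e = mk("e", range(400, 460, 2))
    return [a, b, c, d, e]


@pytest.fixture()
def toy_db():
    db = lc.FingerprintDB(toy_fingerprints(), tolerance=0)
    return db
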