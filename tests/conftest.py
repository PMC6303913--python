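"""Shared fixtures: small corpora and the seeded simulation experiments.

The heavier simulated experiments are session-scoped so the recovery,
symmetry and motif checks all reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import selexkit as sk


def make_rotation_closed_reads(n_base: int = 25, length: int = 40,
                               seed: int = 42) -> sk.RoundReads:
    """A corpus closed under cyclic rotation (n_base * length reads).

    Rotation closure removes read-boundary effects: the m-mer window
    distribution then equals the marginal of the (m+1)-mer window
    distribution exactly, so a pseudocount-free Markov fit reproduces
    empirical j-mer tables to floating-point precision.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_base):
        s = "".join("ACGT"[c] for c in rng.integers(0, 4, length))
        reads.extend(s[i:] + s[:i] for i in range(length))
    return sk.RoundReads(round_index=0, sequences=reads, source="synthetic")


@pytest.fixture(scope="session")
def rotation_corpus() -> sk.RoundReads:
    return make_rotation_closed_reads()


@pytest.fixture(scope="session")
def carg_landscape() -> sk.AffinityLandscape:
    return sk.make_landscape("CCWWWWWWGG", 0.3)


@pytest.fixture(scope="session")
def recovery_experiment(carg_landscape):
    """The parameter-recovery study: uniform 40N library selected on the
    CArG mismatch landscape (factor 0.3), stringency 2, 50,000 reads per
    round, 4 rounds, fixed seed; background fitted on Round 0 and
    relative affinities computed from the final round."""
    config = sk.SimConfig(n_reads_per_round=50_000, n_rounds=4,
                          stringency=2.0, seed=11)
    rounds = sk.run_selex(config, carg_landscape)
    model = sk.fit_markov(rounds[0], order=6, alpha=1.0,
                          strand_mode="collapsed")
    table = sk.count_kmers(rounds[-1], k=10, strand_mode="collapsed")
    affinities = sk.relative_affinity(table, model, min_count=2)
    return {"config": config, "landscape": carg_landscape, "rounds": rounds,
            "model": model, "table": table, "affinities": affinities}


@pytest.fixture(scope="session")
def null_experiment():
    """No-enrichment control: constant landscape, two rounds."""
    landscape = sk.constant_landscape(10)
    config = sk.SimConfig(n_reads_per_round=50_000, n_rounds=2,
                          stringency=1.0, seed=5)
    rounds = sk.run_selex(config, landscape)
    model = sk.fit_markov(rounds[0], order=6, alpha=1.0,
                          strand_mode="collapsed")
    table = sk.count_kmers(rounds[-1], k=10, strand_mode="collapsed")
    affinities = sk.relative_affinity(table, model, min_count=2)
    return {"rounds": rounds, "model": model, "table": table,
            "affinities": affinities}


@pytest.fixture()
def uniform_reads():
    rng = np.random.default_rng(7)
    codes = rng.integers(0, 4, (2000, 40), dtype=np.uint8)
    return sk.RoundReads.from_codes(codes, round_index=0)
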