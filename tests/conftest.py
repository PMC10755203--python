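"""Shared fixtures: tiny simulated studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gbsmap.simulate import (
    SimConfig,
    fragment_reference,
    simulate_f2_population,
    simulate_parents,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Two 60-kb chromosomes, 12 individuals: seconds-fast end-to-end data."""
    return SimConfig(
        n_chromosomes=2,
        chromosome_length=60_000,
        snv_rate=0.005,
        n_individuals=12,
        crossover_mean=0.5,
        mean_depth=8.0,
        n_contigs=6,
        min_contig_length=5_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_cfg):
    truth = simulate_parents(tiny_cfg)
    simulate_f2_population(truth, tiny_cfg)
    return truth


@pytest.fixture(scope="session")
def tiny_assembly(tiny_cfg, tiny_truth):
    contigs, layout, chim = fragment_reference(tiny_truth, tiny_cfg, chimeras=[])
    return contigs


def f2_locus_pair(rng: np.random.Generator, n: int, r: float):
    """Independent oracle for two-locus F2 genotypes at recombination
    fraction r: each parent transmits a two-locus gamete, recombinant with
    probability r.  Returns two code vectors over {0:A,1:H,2:B}."""
    x = np.empty(n, dtype=np.uint8)
    y = np.empty(n, dtype=np.uint8)
    for i in range(n):
        g = np.empty((2, 2), dtype=np.uint8)
        for gi in range(2):
            a1 = rng.integers(0, 2)
            a2 = a1 if rng.random() >= r else 1 - a1
            g[gi] = (a1, a2)
        x[i] = g[0, 0] + g[1, 0]
        y[i] = g[0, 1] + g[1, 1]
    return x, y
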