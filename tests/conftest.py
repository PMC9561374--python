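"""Shared fixtures: small seeded experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from museq.simdata import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_diploid():
    """A small diploid experiment with realistic error rates (seeded)."""
    config = SimulationConfig(
        region_length=1500,
        ploidy=2,
        snv_density=2.0,
        indel_density=0.5,
        templates_per_haplotype_per_strand=6,
        per_template_coverage=100,
        unmutated_coverage=60,
        seed=3,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def clean_diploid():
    """Error-free small diploid experiment (replication rates zero)."""
    config = SimulationConfig(
        region_length=1500,
        ploidy=2,
        snv_density=2.0,
        indel_density=0.0,
        templates_per_haplotype_per_strand=5,
        pcr_snv_rate=0.0,
        pcr_indel_rate=0.0,
        per_template_coverage=100,
        unmutated_coverage=60,
        seed=17,
    )
    return simulate_experiment(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiling_reads(sequence: str, read_length: int = 150, step: int = 20):
    """Deterministic dense read tiling of one sequence (both ends covered)."""
    reads = [
        sequence[i : i + read_length]
        for i in range(0, max(1, len(sequence) - read_length + 1), step)
    ]
    if len(sequence) >= read_length:
        reads.append(sequence[-read_length:])
    return reads
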