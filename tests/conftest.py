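"""Shared fixtures: a small simulated study reused across test modules."""

from __future__ import annotations

import pytest

from grcfinder.simulate import (
    GeneModel,
    GrcSegment,
    SimConfig,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study with one of each planted feature."""
    return SimConfig(
        seed=7,
        a_genome={"A1": 60_000, "A2": 40_000},
        grc_segments=(
            GrcSegment("A1", 5_000, 15_000, divergence=0.01, copy_number=1),
            GrcSegment("A1", 30_000, 36_000, divergence=0.01, copy_number=3),
            GrcSegment("A2", 10_000, 16_000, divergence=0.005, copy_number=2,
                       copy_divergence=0.02),
        ),
        repeat_monomer="ACGGTTAGGGTTAGGGTTACCCTAACCCTAAC",
        repeat_array_length=2_000,
        gene_models=(
            GeneModel("g_full", "A2", ((20_001, 20_601),), fraction_retained=1.0),
            GeneModel("g_half", "A2", ((25_000, 25_600),), fraction_retained=0.5),
            GeneModel("g_stop", "A2", ((30_002, 30_602),), fraction_retained=1.0,
                      premature_stop=True),
        ),
        germline_a_depth=30.0,
        soma_depth=20.0,
        grc_singlecopy_ratio=0.2,
        error_rate=0.0,
        n_samples=2,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_config, small_genome):
    _, _, truth = small_genome
    return simulate_reads(small_config, truth)
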