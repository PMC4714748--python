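import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bsmethyl as bm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(rows):
    """Build a CountTable from (contig, pos, strand, context, mc, cov) tuples."""
    return bm.CountTable(
        pd.DataFrame(rows, columns=["contig", "pos", "strand", "context", "mc", "cov"])
    )


@pytest.fixture(scope="session")
def small_config():
    return bm.SimulationConfig(
        n_contigs=1,
        contig_length=40_000,
        control_contig_length=10_000,
        n_regions=4,
        region_length_range=(2_000, 3_000),
        region_level_range=(0.8, 0.8),
        coverage_lambda=20.0,
        nonconversion_rate=0.005,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(genome, truth, table): one simulated sample over a small genome."""
    genome, truth = bm.generate_genome(small_config)
    table = bm.simulate_count_table(truth, 20.0, 0.005, seed=12)
    return genome, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
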