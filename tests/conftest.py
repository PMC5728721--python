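"""Shared fixtures: one small and one default-scale synthetic study.

Everything is generated at test time from fixed seeds; no data files ship
with the package.
"""

import pytest

from nucmeth import simulate

SEED = 0


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A 60 kb genome: fast enough for per-module unit tests."""
    return simulate.SimulationConfig(seed=SEED, chrom_sizes={"chr1": 60_000})


@pytest.fixture(scope="session")
def small_layout(small_config):
    return simulate.generate_layout(small_config)


@pytest.fixture(scope="session")
def small_nmap(small_config, small_layout):
    return simulate.simulate_true_nucleosomes(small_layout, small_config)


@pytest.fixture(scope="session")
def small_fragments(small_config, small_nmap):
    return simulate.simulate_fragments(small_nmap, small_config,
                                       n_replicates=2)


@pytest.fixture(scope="session")
def wt_records(small_config, small_layout, small_nmap):
    return simulate.simulate_methylome(small_layout, small_nmap, "WT",
                                       small_config)


@pytest.fixture(scope="session")
def h1ddm1_records(small_config, small_layout, small_nmap):
    return simulate.simulate_methylome(small_layout, small_nmap, "h1ddm1",
                                       small_config)
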