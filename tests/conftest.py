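import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haploqtl.config import SimConfig
from haploqtl.simulate import simulate_phenotypes, simulate_population

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> SimConfig:
    """A scaled-down panel that keeps the full three-subpopulation structure."""
    base = dict(
        n_wa=40, n_lr=40, n_rc=60,
        n_chromosomes=4, chrom_length_bp=20_000_000, snp_count=400,
        n_qtl=6, n_emerged_lr=1, n_excluded_lr=1,
        n_emerged_rc=1, n_excluded_rc=1, n_recovered_rc=1,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_panel():
    """One full-size simulated panel shared by the read-only tests."""
    config = SimConfig(seed=0, snp_count=600, n_chromosomes=6,
                       chrom_length_bp=30_000_000)
    panel, truth = simulate_population(config)
    return config, panel, truth


@pytest.fixture(scope="session")
def sim_phenotypes(sim_panel):
    config, panel, truth = sim_panel
    table = simulate_phenotypes(panel, truth, config)
    return config, panel, truth, table
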