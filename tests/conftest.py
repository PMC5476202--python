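import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cocultureseq import (  # noqa: E402
    KmerSpeciesClassifier,
    SimulationConfig,
    generate_genomes,
    simulate_expression,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_species=3,
        genome_length_bp=25_000,
        n_genes=30,
        gene_length_range=(300, 600),
        divergence=0.10,
        depth_mono=2_000,
        depth_mixed=3_000,
        mixtures=[(0, 1, 2)],
        effect_config={"n_straw_induced": 5, "n_mixed_down": 3, "n_mixed_up": 2},
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_genomes(tiny_cfg):
    return generate_genomes(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_expression(tiny_cfg, tiny_genomes):
    return simulate_expression(tiny_cfg, tiny_genomes)


@pytest.fixture(scope="session")
def tiny_classifier(tiny_genomes):
    return KmerSpeciesClassifier().fit(tiny_genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
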