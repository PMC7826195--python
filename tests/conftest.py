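"""Shared fixtures: small synthetic gene sets and printed study inputs."""

import numpy as np
import pytest

from genedecay import SimulationScenario, generate_gene_set

#: relative LoF rates (units of mu per coding site) as estimated for the
#: Lucifuga vision gene set: premature stop, frameshift, splice, start, stop
PRINTED_RELATIVE_RATES = (0.031, 0.0143, 0.0212, 0.0028, 0.0023)
PRINTED_MEAN_LENGTH = 1091
PRINTED_MU = 1e-8
PRINTED_KAPPA = 4.57

#: observed LoF-mutations-per-gene vectors among 76 vision genes
DENTATA_COUNTS = [57, 16, 3]
GIBARENSIS_COUNTS = [71, 3, 2]


@pytest.fixture(scope="session")
def printed_mu_lof() -> float:
    return sum(PRINTED_RELATIVE_RATES) * PRINTED_MEAN_LENGTH * PRINTED_MU


@pytest.fixture(scope="session")
def vision_gene_set():
    """A 76-gene set with the study's length/intron distributions."""
    return generate_gene_set(SimulationScenario(seed=101))


@pytest.fixture(scope="session")
def small_gene_set():
    """A quick 12-gene set for scan/score unit tests."""
    return generate_gene_set(
        SimulationScenario(n_genes=12, length_mean=450.0, intron_mean=2.0, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
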