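import numpy as np
import pytest

import cytoscreen as cs


@pytest.fixture(scope="session")
def pbmc_populations():
    return cs.load_population_tree("pbmc_composition")


@pytest.fixture(scope="session")
def tcell_populations():
    return cs.load_population_tree("tcell_composition")


@pytest.fixture(scope="session")
def pbmc_gating_tree():
    return cs.load_gating_tree("pbmc_tree")


@pytest.fixture(scope="session")
def tcell_gating_tree():
    return cs.load_gating_tree("tcell_tree")


@pytest.fixture(scope="session")
def pbmc_donor(pbmc_populations):
    """One seeded healthy donor, 30k events, no composition jitter."""
    donor = cs.DonorSpec("D1", composition_jitter=0.0, seed=7)
    return cs.generate_donor_events(pbmc_populations, donor, 30_000)


@pytest.fixture(scope="session")
def pbmc_gated(pbmc_donor, pbmc_gating_tree):
    return cs.apply_gating(pbmc_donor, pbmc_gating_tree, seed=0)


@pytest.fixture(scope="session")
def random_signatures():
    rng = np.random.default_rng(123)
    return [cs.SpectralSignature(f"F{i}", rng.random(12)) for i in range(4)]
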