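import numpy as np
import pytest

from fracsynth import pools as pools_mod
from fracsynth.simulate import DEFAULT_POOLS, SimConfig


@pytest.fixture(scope="session")
def default_pool_table():
    """Pool enrichment table mirroring the study's GC–MS observations."""
    return pools_mod.AAEnrichmentTable.from_dict(DEFAULT_POOLS)


@pytest.fixture(scope="session")
def noiseless_config():
    """Tiny noise-free study: 4 proteins × 3 Lys-C peptides, 2 conditions."""
    return SimConfig(seed=7, n_proteins=4, peptides_per_protein=3, cv=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
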