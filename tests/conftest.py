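import pytest
from hypothesis import HealthCheck, settings

import decayatlas as da

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def expectation_dataset() -> da.SimulatedDataset:
    """Noiseless 200-gene dataset shared across oracle tests."""
    truth = da.generate_gene_params(n_genes=200, seed=7)
    return da.simulate_dataset(truth, da.SimulationConfig(seed=7, mode="expectation"))


@pytest.fixture(scope="session")
def expectation_fpkm(expectation_dataset) -> da.FpkmMatrix:
    return da.compute_fpkm(expectation_dataset.exonic, expectation_dataset.gene_lengths)
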