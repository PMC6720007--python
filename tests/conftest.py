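import pytest

from mirnet import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    """A fast end-to-end scenario: fewer miRNAs/genes, same cohort shape."""
    return sd.SimulationConfig(seed=11, n_mirnas=200, n_negctrl_probes=20,
                               n_genes=80, n_communities=4)


@pytest.fixture(scope="session")
def small_truth(small_config):
    matrix, truth = sd.generate_expression(small_config)
    return matrix, truth


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A default-condition bundle on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = sd.simulate_bundle(sd.SimulationConfig(seed=42), outdir)
    return outdir, truth
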