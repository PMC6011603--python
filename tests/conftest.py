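import pytest

from saltomics.pipeline import run_all
from saltomics.synthetic import SimConfig, noise_free_config, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One default-noise synthetic dataset shared across tests."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """The noise-free limit of the default configuration."""
    return simulate_all(noise_free_config(seed=5))


def _run(ds):
    return run_all(
        ds.expression,
        ds.proteins,
        ds.mirna_counts,
        ds.mirna_seqs,
        ds.cds_seqs,
        ds.as_events,
        ds.ortholog_map,
        ds.ppi_edges,
    )


@pytest.fixture(scope="session")
def noise_free_result(noise_free_dataset):
    """Full pipeline output on the noise-free dataset."""
    return _run(noise_free_dataset)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return _run(default_dataset)
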