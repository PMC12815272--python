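import pytest

from denovofocus.simulate import (
    Reference,
    SimulationConfig,
    make_reference,
    make_taxonomy,
    simulate_study,
    write_fixture_dir,
)
from denovofocus.taxonomy import TaxonNode, TaxonomyStore


@pytest.fixture(scope="session")
def toy_store() -> TaxonomyStore:
    """Hand-built chain: species 10/11 < genus 5 < family 3 < Bacteria."""
    return TaxonomyStore(
        [
            TaxonNode(1, 1, "no_rank", "root"),
            TaxonNode(2, 1, "superkingdom", "Bacteria"),
            TaxonNode(3, 2, "family", "Toyfamily"),
            TaxonNode(5, 3, "genus", "Toygenus"),
            TaxonNode(10, 5, "species", "Toygenus one"),
            TaxonNode(11, 5, "species", "Toygenus two"),
            TaxonNode(4, 1, "superkingdom", "Eukaryota"),
            TaxonNode(20, 4, "species", "Euk species"),
        ]
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_store(sim_config) -> TaxonomyStore:
    return make_taxonomy(sim_config)


@pytest.fixture(scope="session")
def sim_reference(sim_config, sim_store) -> Reference:
    return make_reference(sim_config, sim_store)


@pytest.fixture(scope="session")
def sim_study(sim_config, sim_reference, sim_store):
    """(samples, ground truth) of the default error-free study design."""
    return simulate_study(sim_config, sim_reference, sim_store)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    """A complete fixture tree on disk, as the CLI would generate it."""
    path = tmp_path_factory.mktemp("fixtures")
    return write_fixture_dir(sim_config, path)
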