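import pytest

from indelmark import SimulationConfig, discover, simulate_study
from indelmark.pipeline import genotype_population


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale-in-miniature study conditions shared across tests."""
    return SimulationConfig(
        seed=11,
        n_chromosomes=4,
        chromosome_length_bp=60_000,
        n_parental_indels=300,
        n_progeny=30,
    )


@pytest.fixture(scope="session")
def study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def discovery_result(study):
    return discover(
        study.parents.maternal_table,
        study.parents.paternal_table,
        study.progeny.tables,
        gene_models=study.parents.gene_models,
    )


@pytest.fixture(scope="session")
def genotyped(study, discovery_result):
    matrix, primers = genotype_population(
        study.parents.reference,
        discovery_result.markers,
        study.parents.maternal_table,
        study.parents.paternal_table,
        study.progeny.tables,
    )
    return matrix, primers


@pytest.fixture(scope="session")
def sim_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    study.write(str(out))
    return out
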