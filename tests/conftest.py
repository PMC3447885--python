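import pytest

from zincluster.connectivity import MSL2_ASSIGNMENT
from zincluster.synthetic import (
    GeneratorConfig,
    make_cluster_coordinates,
    msl2_connectivity_input,
)


@pytest.fixture(scope="session")
def ideal_ensemble():
    """Noise-free trinuclear cluster, 2 identical models."""
    return make_cluster_coordinates(GeneratorConfig(n_models=2))


@pytest.fixture(scope="session")
def ideal_model(ideal_ensemble):
    return ideal_ensemble[0]


@pytest.fixture()
def msl2_dataset():
    """Solver input with metal C's two unseen ligands hidden."""
    return msl2_connectivity_input()


@pytest.fixture(scope="session")
def msl2_assignment():
    return MSL2_ASSIGNMENT
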