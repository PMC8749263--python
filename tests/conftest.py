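import pytest

from mitoring.catalogs import load_mdp_catalog
from mitoring.synthetic_data import SimPlan, generate_mitogenome


@pytest.fixture(scope="session")
def catalog():
    return load_mdp_catalog()


@pytest.fixture(scope="session")
def base_sim(catalog):
    """One default-plan synthetic mitogenome with its annotations/truth."""
    return generate_mitogenome(SimPlan(seed=7), catalog)


@pytest.fixture(scope="session")
def base_genome(base_sim):
    return base_sim[0]
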