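import pytest

from pedkit import make_example_pedigrees


@pytest.fixture()
def mother_son():
    """Mother-son mating: Cora (founder dam) x her son Bandit -> Jochen."""
    return make_example_pedigrees()["mother_son"]


@pytest.fixture()
def first_cousins():
    """First-cousin mating: grandparents Gm x Gf, sibs P1/P2, cousins C1 x C2."""
    return make_example_pedigrees()["first_cousins"]


@pytest.fixture()
def inbred_chain():
    """Four-generation close-mating chain: Jochen, Merle, Carl, Luise."""
    return make_example_pedigrees()["inbred_chain"]
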