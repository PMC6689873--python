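import pytest

from xenometab import standardize
from xenometab.transformers import default_packs


@pytest.fixture(scope="session")
def packs():
    return default_packs()


@pytest.fixture(scope="session")
def human_kb(packs):
    return packs["human_gut"]


@pytest.fixture(scope="session")
def env_kb(packs):
    return packs["env"]


@pytest.fixture(scope="session")
def mol():
    """Factory fixture: standardized molecule from SMILES (cached)."""
    cache = {}

    def build(smiles: str):
        if smiles not in cache:
            cache[smiles] = standardize(smiles)
        return cache[smiles]

    return build


EPICATECHIN = "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2"
ACETAMINOPHEN = "CC(=O)Nc1ccc(O)cc1"
KAEMPFEROL_DME_GLUCOSIDE = (
    "COc1ccc(-c2oc3cc(OC)cc(O)c3c(=O)c2OC2OC(CO)C(O)C(O)C2O)cc1"
)
TRIESTER = "CC(=O)OCC(COC(=O)CCC)OC(=O)CC"
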