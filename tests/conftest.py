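import numpy as np
import pytest

from molgraphgen import fixtures as F
from molgraphgen.molgraph import build_vocab
from molgraphgen.policy import MolMP, MolRNN, PolicyConfig

# molecules of at most four heavy atoms: small enough for exhaustive
# route enumeration
TINY_MOLS = ["C", "CC", "CCO", "C=O", "CCN", "CC=O", "C#N", "CO", "CN",
             "CCC"]


@pytest.fixture(scope="session")
def bundled():
    return F.bundled_corpus()


@pytest.fixture(scope="session")
def tiny_vocab():
    return build_vocab(TINY_MOLS)


@pytest.fixture(scope="session")
def drug_vocab(bundled):
    return build_vocab(bundled)


@pytest.fixture
def tiny_molmp(tiny_vocab):
    return MolMP(tiny_vocab, PolicyConfig.desk(), np.random.default_rng(5))


@pytest.fixture
def tiny_molrnn(tiny_vocab):
    return MolRNN(tiny_vocab, PolicyConfig.desk(), np.random.default_rng(6))
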