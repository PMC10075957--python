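import numpy as np
import pytest

from chima.chem import PeptideForm, default_modifications
from chima.proteolysis import bundled_histones


@pytest.fixture(scope="session")
def mods():
    return default_modifications()


@pytest.fixture(scope="session")
def histones():
    return bundled_histones()


@pytest.fixture(scope="session")
def isomer_pair(mods):
    """The classic chimeric pair: K(la)STGGK(ac)APR and K(ac)STGGK(la)APR."""
    a = PeptideForm("KSTGGKAPR", mods=((1, mods["la"]), (6, mods["ac"])))
    b = PeptideForm("KSTGGKAPR", mods=((1, mods["ac"]), (6, mods["la"])))
    return a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_peptide(rng, min_len=6, max_len=15):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
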