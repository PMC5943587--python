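import numpy as np
import pytest

from cdbalance import GravimetricPrep, protein_constants_from_sequences

# porcine insulin: A and B chains, three disulfide bonds, three Phe residues
PINS_A = "GIVEQCCTSICSLYQLENYCN"
PINS_B = "FVNQHLCGSHLVEALYLVCGERGFFYTPKA"


@pytest.fixture(scope="session")
def pins_spec():
    return protein_constants_from_sequences([PINS_A, PINS_B], name="pINS", n_disulfides=3)


@pytest.fixture(scope="session")
def pins_prep():
    # 200 mg sample aliquot + 50 mg internal standard + 850 mg acid in the
    # ampoule; 12 mg solid protein diluted to 1000 mg
    return GravimetricPrep(m_total=1100.0, m_sample=200.0, m_diluted=1000.0, m_solid=12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
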