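import numpy as np
import pytest

from thermotraj.io import perceive_topology
from thermotraj.synthetic import generate_peptide


@pytest.fixture(scope="session")
def helix20():
    """20-residue ideal alpha-helix with perceived topology."""
    peptide = generate_peptide(20, "helix")
    topology, peptide = perceive_topology(peptide)
    return peptide, topology


@pytest.fixture(scope="session")
def helix12():
    peptide = generate_peptide(12, "helix")
    topology, peptide = perceive_topology(peptide)
    return peptide, topology


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
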