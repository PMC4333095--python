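import numpy as np
import pytest

from ztrekit import fixtures
from ztrekit.sequence_io import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def probe():
    """The bundled 202-nt SLC30A5 promoter probe (−156..+46)."""
    return fixtures.slc30a5_probe()


@pytest.fixture(scope="session")
def probe_deletion():
    """The probe with the 5' side of the ZTRE (−91..−84) deleted."""
    return fixtures.slc30a5_probe_deletion()


@pytest.fixture(scope="session")
def ztre():
    return fixtures.ztre_consensus()


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def dna_record(rng):
    return SequenceRecord(id="r", alphabet="DNA", residues=random_dna(rng, 200))
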