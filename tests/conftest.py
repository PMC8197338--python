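import numpy as np
import pytest

from cypcensus import synthetic_data
from cypcensus.refdb_io import ReferenceDB

REF_NAMES = ("CYP202A1", "CYP153A1", "CYP108A1", "CYP173A1", "CYP1101A1", "CYP125A1")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def refdb() -> ReferenceDB:
    """Six mutually unrelated named references (chance-level identity)."""
    return synthetic_data.generate_reference_db(REF_NAMES, length=420, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=length))
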