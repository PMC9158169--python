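import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hmpi.encoders import load_property_table, standardize_table
from hmpi.sequence_io import SequenceRecord


@pytest.fixture(scope="session")
def table():
    """The bundled property table, standardized."""
    return standardize_table(load_property_table())


@pytest.fixture(scope="session")
def raw_table():
    return load_property_table()


def random_records(n, length, seed, label="x"):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return [
        SequenceRecord(
            id=f"r{i}", sequence="".join(bases[rng.integers(4, size=length)]), label=label
        )
        for i in range(n)
    ]


@pytest.fixture
def records_81():
    return random_records(20, 81, seed=11)
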