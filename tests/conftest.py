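import numpy as np
import pytest
from hypothesis import settings

from rnaloc.io import MrnaRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_record(rng, length, alphabet="ACGT", rec_id="r"):
    seq = "".join(rng.choice(list(alphabet), size=length))
    return MrnaRecord(id=rec_id, sequence=seq)


@pytest.fixture
def random_records():
    """Factory: n seeded random records with lengths in [lo, hi]."""

    def make(n, lo, hi, alphabet="ACGT", seed=0):
        rng = np.random.default_rng(seed)
        return [
            random_record(rng, int(rng.integers(lo, hi + 1)), alphabet, f"r{i}")
            for i in range(n)
        ]

    return make


@pytest.fixture
def worked_example():
    """The 7-nt sequence used in the hand-worked feature examples."""
    return MrnaRecord(id="m1", sequence="ACGCCGC")
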