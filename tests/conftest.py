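import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrembed import ALPHABET, SequenceRecord, SequenceSet

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

WORKED_EXAMPLE = "CASSATGNEQFF"


@pytest.fixture
def worked_example() -> str:
    return WORKED_EXAMPLE


@pytest.fixture
def random_sequences():
    """Factory for sets of random sequences over the amino-acid alphabet."""

    def make(n: int, seed: int = 0, min_len: int = 4, max_len: int = 30) -> SequenceSet:
        rng = np.random.default_rng(seed)
        letters = np.array(list(ALPHABET))
        records = []
        for i in range(n):
            length = rng.integers(min_len, max_len + 1)
            records.append(
                SequenceRecord(f"r{i}", "".join(rng.choice(letters, size=length)))
            )
        return SequenceSet(records)

    return make
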