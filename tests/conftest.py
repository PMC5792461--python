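import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fecalrad.genome import ReferenceSequence

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_contig() -> ReferenceSequence:
    """18 bp contig with one SphI site (cut at 7) and one MluCI site (cut at 12)."""
    return ReferenceSequence({"c1": "TTGCATGCTTTTAATTTT"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_genome(length: int, seed: int, gc: float = 0.4) -> ReferenceSequence:
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    return ReferenceSequence({"chr1": seq})
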