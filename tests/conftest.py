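import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chipfrag.seq_io import GenomeAssembly, SequenceRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    return GenomeAssembly(
        (
            SequenceRecord("chr1", random_dna(rng, 3000)),
            SequenceRecord("chr2", random_dna(rng, 1700)),
        )
    )
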