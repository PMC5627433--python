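import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blockspec import AMINO_ACIDS, SubstrateSet, SubstrateWindow

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_gapfree_set(rng: np.random.Generator, n: int,
                       protease_id: str = "random") -> SubstrateSet:
    """n windows drawn uniformly over the 20 amino acids, no gaps."""
    mat = rng.integers(0, len(AMINO_ACIDS), size=(n, 8))
    windows = [SubstrateWindow("".join(AMINO_ACIDS[i] for i in row)) for row in mat]
    return SubstrateSet(protease_id, windows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
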