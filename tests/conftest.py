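import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tediv.msa import MSA, PairAlignment

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_msa() -> MSA:
    return MSA(
        [
            ("human", "ACGT--ACGTAC"),
            ("chimp", "ACGTTTACG--C"),
            ("lemur", "A--TTTACGTAC"),
        ]
    )


def random_pair(rng: np.random.Generator, max_cols: int = 30) -> PairAlignment:
    """A random mutually de-gapped pair alignment (for oracle comparisons)."""
    n = int(rng.integers(1, max_cols + 1))
    cols_a, cols_b = [], []
    for _ in range(n):
        state = rng.random()
        if state < 0.2:
            cols_a.append("-")
            cols_b.append("ACGT"[rng.integers(4)])
        elif state < 0.4:
            cols_a.append("ACGT"[rng.integers(4)])
            cols_b.append("-")
        else:
            cols_a.append("ACGT"[rng.integers(4)])
            cols_b.append("ACGT"[rng.integers(4)])
    return PairAlignment("a", "b", "".join(cols_a), "".join(cols_b))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230314)
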