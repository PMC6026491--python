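import numpy as np
import pytest

from tfcoop.motif import ALPHABET, PSSM
from tfcoop.simulate import SimConfig, generate_study


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[b] for b in rng.integers(0, 4, n))


def random_pssm(rng: np.random.Generator, w: int, sharpness: float = 0.9) -> PSSM:
    consensus = rng.integers(0, 4, w)
    mat = np.full((w, 4), (1 - sharpness) / 3)
    mat[np.arange(w), consensus] = sharpness
    return PSSM("M", mat)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact study used by fast unit tests."""
    return SimConfig(seed=42, n_genes=150, regulon_size=20)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One study at the default conditions (shared, read-only)."""
    return generate_study(SimConfig(seed=0))
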