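import numpy as np
import pytest

from sixma.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_benchmark():
    """A small but learnable synthetic benchmark shared across tests."""
    return generate(SimConfig(n_pos=60, n_neg=60, effect_size=0.8, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_window(rng: np.random.Generator, length: int = 41, center_a: bool = True) -> str:
    seq = rng.choice(list("ACGT"), size=length)
    if center_a:
        seq[(length - 1) // 2] = "A"
    return "".join(seq)
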