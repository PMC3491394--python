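import numpy as np
import pytest

from promfunc import build_pwm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def acg_pwm():
    """Deterministic width-3 PWM with consensus ACG."""
    return build_pwm([[8, 0, 0, 0], [0, 8, 0, 0], [0, 0, 8, 0]], name="ACG")


@pytest.fixture
def soft_pwm():
    """Informative but non-degenerate width-4 PWM (pseudocounted)."""
    counts = [[12, 2, 2, 2], [2, 12, 2, 2], [2, 2, 12, 2], [2, 2, 2, 12]]
    return build_pwm(counts, pseudocount=0.5, name="soft")


def random_sequence(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
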