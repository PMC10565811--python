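import numpy as np
import pytest

from gepqsar.tables import DescriptorTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n, p, prefix="X"):
    """Small random descriptor table with standard-normal columns."""
    values = rng.standard_normal((n, p))
    activity = rng.standard_normal(n)
    return DescriptorTable(
        tuple(f"c{i}" for i in range(n)),
        tuple(f"{prefix}{j}" for j in range(p)),
        values,
        activity,
    )


@pytest.fixture
def small_table(rng):
    return random_table(rng, 15, 4)
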