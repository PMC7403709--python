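import numpy as np
import pandas as pd
import pytest

from pathosig.synthetic import TextureClassParams, generate_tile_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def he_tile():
    """A small textured H&E-like tile shared across tests."""
    return generate_tile_image(TextureClassParams(), seed=7, size=96)


@pytest.fixture(scope="session")
def planted_features():
    """Feature table with 2 informative and 102 noise columns, n=500."""
    gen = np.random.default_rng(42)
    n, p = 500, 104
    X = pd.DataFrame(
        gen.normal(size=(n, p)), columns=[f"f{i:03d}" for i in range(p)]
    )
    y = gen.integers(0, 2, n)
    X["f000"] += 1.5 * y
    X["f001"] -= 1.5 * y
    return X, y
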