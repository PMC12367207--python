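import numpy as np
import pytest

from airpls_opt import SyntheticShapeSpec, generate_spectrum


@pytest.fixture(scope="session")
def be_spectrum():
    """A broad-peak/exponential-baseline spectrum (the hardest family)."""
    return generate_spectrum(
        SyntheticShapeSpec.from_label("B&E", rng_seed=5, n_points=512)
    )


@pytest.fixture(scope="session")
def dp_spectrum():
    """A distinct-peak/polynomial-baseline spectrum (easy to optimize)."""
    return generate_spectrum(
        SyntheticShapeSpec.from_label("D&P", rng_seed=7, n_points=512)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
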