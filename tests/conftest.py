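import numpy as np
import pytest

from moscreen import SyntheticLibrarySpec, generate_library


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast three-objective benchmark library (n=300, d=8)."""
    spec = SyntheticLibrarySpec(n_molecules=300, d=8, n_objectives=3,
                                smoothness=(30.0, 30.0, 30.0), seed=11)
    return generate_library(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
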