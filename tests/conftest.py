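import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_series():
    """A small synthetic multi-scan dataset with one planted triad of
    each kind, shared across tests that only need plausible input."""
    from syntopo.bold import SyntheticSpec, generate_bold

    spec = SyntheticSpec(
        n_parcels=10, scan_length=300, n_scans=4, ar_coefficient=0.6,
        planted_redundant=(((0, 1, 2), 0.9),),
        planted_synergistic=(((3, 4, 5), 0.1),),
        seed=7,
    )
    return generate_bold(spec)
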