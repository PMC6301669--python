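import numpy as np
import pytest

import hupotency as hp


@pytest.fixture(scope="session")
def powder_table():
    return hp.load_powder_table()


@pytest.fixture(scope="session")
def experiment():
    """The full powder-table analysis (projection, SVD, BIC)."""
    return hp.run_experimental_analysis()


@pytest.fixture(scope="session")
def synthetic_model():
    """Synthetic acquisition model with a 20 mm Al filter."""
    return hp.build_synthetic_model(filter_thickness=0.02)


@pytest.fixture(scope="session")
def synthetic_potencies(synthetic_model):
    """13-element x 4-voltage theoretical potency matrix."""
    return hp.element_potency_matrix(synthetic_model, hp.STUDY_ELEMENTS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
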