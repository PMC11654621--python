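import numpy as np
import pytest

import omicbridge as ob


@pytest.fixture(scope="session")
def small_study():
    """Unpaired 3-cluster study small enough for per-test use."""
    return ob.default_study(seed=0, n_cells=300)


@pytest.fixture(scope="session")
def small_paired_study():
    return ob.default_study(seed=0, n_cells=300, paired=True)


@pytest.fixture(scope="session")
def standard_study():
    """The standard fixture: K=3, M=2, C=10, 3000 cells per modality."""
    study = ob.default_study(seed=0, n_cells=3000)
    for v in study.modalities:
        ob.eigenmap_order(v)
    from omicbridge.pairing import harmonize_eigenmap_signs
    harmonize_eigenmap_signs(study)
    return study


@pytest.fixture
def rng():
    return np.random.default_rng(0)
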