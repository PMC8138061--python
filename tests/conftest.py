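import numpy as np
import pytest

from msdiffusion import make_gradient_table, simulate_dwi
from msdiffusion.phantom import Lesion, default_phantom


@pytest.fixture(scope="session")
def gtab():
    """Reference single-shell acquisition: b=1000, 3 b0, 45 directions."""
    return make_gradient_table(n_dirs=45, n_b0=3, b=1000.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom(gtab):
    """Small mirrored phantom with one lesion, no noise; shared across tests."""
    spec = default_phantom(
        lesions=(Lesion(center=(10, 20, 8), radius=3.0),),
        grid_shape=(40, 40, 16),
        snr=np.inf,
    )
    dwi, truth = simulate_dwi(spec, gtab, seed=1)
    return spec, dwi, truth
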