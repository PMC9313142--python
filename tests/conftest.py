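import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from psma_percist import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise-free phantom with lesions of true volume ~{0.2, 0.5, 1.0} mL.

    Sphere radii chosen so the analytic volumes are 0.2/0.5/1.0 mL; with
    2 mm voxels the digitized volumes straddle the 0.3 mL filter the same
    way (only the smallest lesion falls below it).
    """
    radii = [(3 * v * 1000 / (4 * np.pi)) ** (1 / 3) for v in (0.2, 0.5, 1.0)]
    spec = phantom.PhantomSpec(
        grid_shape=(48, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        background_mean=1.0,
        background_sd=0.0,
        aorta=phantom.AortaSpec(center=(48.0, 40.0, 64.0), mean=2.0, sd=0.0),
        lesions=(
            phantom.LesionSpec(center=(30.0, 90.0, 40.0), radii=(radii[0],) * 3,
                               intensity=10.0, site="bone"),
            phantom.LesionSpec(center=(60.0, 40.0, 90.0), radii=(radii[1],) * 3,
                               intensity=10.0, site="bone"),
            phantom.LesionSpec(center=(70.0, 90.0, 95.0), radii=(radii[2],) * 3,
                               intensity=10.0, site="lymph_node"),
        ),
        seed=0,
    )
    return phantom.generate_phantom(spec)
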