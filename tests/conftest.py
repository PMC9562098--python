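import numpy as np
import pytest

from ridgemetry import PhantomParams, generate_phantom_volume

# compact phantom geometry used throughout the suite: 224 axial samples at
# 4.4 um/px give a ~985 um axial field, enough for a 200 um retina plus a
# 600 um ridge with margins
SMALL = dict(n_axial=224, n_fast=80, n_slow=80, baseline_retina_um=200.0)


def small_params(**overrides) -> PhantomParams:
    kwargs = {**SMALL, **overrides}
    return PhantomParams(**kwargs)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """A ridge phantom rendered without speckle, with its ground truth."""
    params = small_params(ridge_height_um=300.0, speckle_snr=np.inf)
    volume, truth = generate_phantom_volume(params, seed=11)
    return params, volume, truth


@pytest.fixture(scope="session")
def speckled_phantom():
    """The same geometry at the default speckle level."""
    params = small_params(ridge_height_um=300.0)
    volume, truth = generate_phantom_volume(params, seed=12)
    return params, volume, truth
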