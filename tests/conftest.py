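import numpy as np
import pytest

from petburden.phantom import Ellipsoid, PhantomSpec, generate_phantom
from petburden.suv import SuvVolume


@pytest.fixture
def noiseless_spec():
    """Three disjoint uniform lesions, no blur, no noise, flat background."""
    return PhantomSpec(
        grid_shape=(50, 50, 50),
        spacing_mm=(2.0, 2.0, 2.0),
        background_suv=(1.0, 0.0),
        # liver radii exceed the 15 mm reference-sphere radius so the sphere
        # samples pure liver
        liver=Ellipsoid((30, 30, 30), (20, 18, 16), 2.0, 0.0, label="liver", name="liver"),
        lesions=[
            Ellipsoid((70, 70, 70), (10, 10, 10), 8.0, name="lesion_1"),
            Ellipsoid((20, 70, 20), (8, 6, 6), 6.0, name="lesion_2"),
            Ellipsoid((70, 20, 70), (5, 5, 7), 9.0, name="lesion_3"),
        ],
        smoothing_fwhm_mm=0.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


def make_volume(values, spacing=(2.0, 2.0, 2.0)):
    return SuvVolume(values=np.asarray(values, dtype=float), spacing_mm=spacing)
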