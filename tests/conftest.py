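import numpy as np
import pytest

from dmvquant.phantom import PhantomSpec, generate_vessel_phantom
from dmvquant.reconstruction import MinipSlice


def make_slice(image, spacing_mm=0.703, midline=None):
    return MinipSlice(image=np.asarray(image, float),
                      spacing_mm=(spacing_mm, spacing_mm),
                      slab_center_mm=0.0, slab_thickness_mm=20.0,
                      midline_column=midline)


@pytest.fixture(scope="session")
def fine_spec():
    """Subpixel-accuracy phantom geometry: 0.2 mm pixels, 64 mm FOV."""
    return PhantomSpec(image_shape=(320, 320), spacing_mm=0.2, n_vessels=12)


@pytest.fixture(scope="session")
def fine_phantom(fine_spec):
    image, truth = generate_vessel_phantom(fine_spec, seed=0)
    return fine_spec, image, truth


@pytest.fixture(scope="session")
def coarse_phantom():
    """Acquisition-resolution phantom (0.703 mm pixels, ~1 px vessels)."""
    spec = PhantomSpec()
    image, truth = generate_vessel_phantom(spec, seed=1)
    return spec, image, truth
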