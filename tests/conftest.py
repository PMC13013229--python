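import numpy as np
import pytest
from hypothesis import settings

import dpdquant as dq

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, unblurred default thorax: (volume, structures, truth)."""
    spec = dq.default_thorax(psf_fwhm_mm=0.0)
    return dq.generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_panel(clean_phantom):
    vol, ss, _ = clean_phantom
    return dq.extract_panel(vol, ss)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250922)


def random_geometry(rng, max_side=16, anisotropic=True):
    shape = tuple(int(s) for s in rng.integers(4, max_side + 1, size=3))
    if anisotropic:
        spacing = tuple(float(s) for s in rng.uniform(0.8, 3.0, size=3))
    else:
        spacing = (float(rng.uniform(0.8, 3.0)),) * 3
    origin = tuple(float(o) for o in rng.uniform(-10, 10, size=3))
    return dq.GridGeometry(shape=shape, spacing=spacing, origin=origin)


def random_mask(rng, shape, density=0.05):
    m = rng.random(shape) < density
    if not m.any():
        m[tuple(int(rng.integers(0, s)) for s in shape)] = True
    return m
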