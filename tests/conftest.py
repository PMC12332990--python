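import logging

import numpy as np
import pytest

from adrenalct.io import CTVolume, LabelMask
from adrenalct.phantom import PhantomSpec, generate_phantom

logging.getLogger("adrenalct").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    """Noiseless 48x48x24 phantom with a left nodule (AI positive left)."""
    spec = PhantomSpec(
        dims=(48, 48, 24), spacing=(1.0, 1.0, 3.0), noise_sigma=0.0,
        nodule_left=(15.0, 40.0), seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture
def noisy_phantom():
    spec = PhantomSpec(
        dims=(48, 48, 24), spacing=(1.0, 1.0, 3.0), noise_sigma=6.0,
        nodule_right=(14.0, 50.0), seed=3,
    )
    return generate_phantom(spec)


def random_volume(rng, shape=(12, 10, 8), spacing=(1.0, 1.5, 3.0),
                  orientation="PLI", origin=(0.0, 0.0, 0.0)):
    return CTVolume(
        rng.normal(40, 100, size=shape).astype(np.float32),
        spacing=spacing, orientation=orientation, origin=origin,
    )


def random_mask(rng, shape=(12, 10, 8), p=0.3, **kw):
    return LabelMask(
        (rng.random(shape) < p).astype(np.int16)
        + (rng.random(shape) < p / 2).astype(np.int16),
        **kw,
    )
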