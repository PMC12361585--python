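import dataclasses

import numpy as np
import pytest

from llseg.phantom import PhantomSpec, generate_phantom
from llseg.volume import BinaryMask, CtVolume, InstanceMask

#: small fast grid used by most unit-test phantoms
SMALL_SPEC = PhantomSpec(
    shape=(48, 48, 40),
    spacing=(3.0, 2.5, 2.5),
    n_lesions=2,
    noise_sd=0.0,
    n_tube_distractors=1,
    n_extra_distractors=1,
    seed=7,
)


def small_spec(**overrides) -> PhantomSpec:
    return dataclasses.replace(SMALL_SPEC, **overrides)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free small phantom with two lesions and two distractors."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def lesion_only_phantom():
    """Noise-free phantom without distractor structures."""
    return generate_phantom(small_spec(n_tube_distractors=0, n_extra_distractors=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_mask(rng, shape=(16, 16, 16), density=0.1) -> np.ndarray:
    return rng.random(shape) < density


def as_instance(data, spacing=(1.0, 1.0, 1.0)) -> InstanceMask:
    return InstanceMask(np.asarray(data, dtype=np.uint16), spacing)


def as_binary(data, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(np.asarray(data, dtype=np.uint8), spacing)


def as_volume(data, spacing=(1.0, 1.0, 1.0)) -> CtVolume:
    return CtVolume(np.asarray(data, dtype=np.float32), spacing)
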