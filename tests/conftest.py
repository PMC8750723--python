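"""Shared fixtures: small seeded phantoms at several scales.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from sctsynth.phantom import PhantomSpec, generate_phantom
from sctsynth.preprocess import PreprocessConfig, preprocess_case


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Coarse grid, default mm geometry: fast to generate and process."""
    return PhantomSpec(shape=(12, 48, 48), spacing=(2.5, 6.0, 6.0))


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Mid-resolution grid used by training-related tests."""
    return PhantomSpec(shape=(16, 64, 64), spacing=(2.5, 4.5, 4.5))


@pytest.fixture(scope="session")
def bounded_spec() -> PhantomSpec:
    """Body bounded inside the slice slab, so axial shifts are observable."""
    base = PhantomSpec()  # default 24-slice slab
    geometry = dict(base.geometry)
    geometry["body"] = ((18.0, 82.0, 105.0), (22.0, 95.0, 118.0))
    return replace(base, geometry=geometry)


@pytest.fixture(scope="session")
def zero_noise_case(small_spec):
    return generate_phantom(small_spec.with_zero_noise(), seed=11)


@pytest.fixture(scope="session")
def noisy_case(small_spec):
    return generate_phantom(small_spec, seed=12)


@pytest.fixture(scope="session")
def prep_zero_noise(zero_noise_case):
    return preprocess_case(zero_noise_case, PreprocessConfig(register=False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
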