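"""Shared fixtures: phantoms generated once per session."""

import numpy as np
import pytest

from cordti.phantom import MotionModel, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, motion-free default-geometry phantom (1 repetition)."""
    spec = PhantomSpec(
        n_repetitions=1, noise_sigma=0.0, motion=MotionModel(kind="none"), seed=1
    )
    truth, stack = generate_phantom(spec)
    return spec, truth, stack


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default acquisition: 32 repetitions, Rician noise, random-walk motion."""
    spec = PhantomSpec(seed=5)
    truth, stack = generate_phantom(spec)
    return spec, truth, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
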