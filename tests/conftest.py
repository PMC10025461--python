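import numpy as np
import pytest

from gaitmesh import (GaitProfile, default_gait_profile, generate_walk,
                      add_stickers, make_toy_model)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(1000, seed=1)


@pytest.fixture(scope="session")
def static_recording(toy_model):
    """Noiseless static recording (all gait amplitudes zero)."""
    return generate_walk(toy_model, GaitProfile(cadence_hz=1.2),
                         duration_s=0.5, fps=30, noise_sd=0.0, seed=2,
                         n_points=800, include_floor=False)


@pytest.fixture(scope="session")
def walk_recording(toy_model):
    """Short noisy walk with floor and stickers (no robot parts)."""
    rec = generate_walk(toy_model, default_gait_profile(), duration_s=1.0,
                        fps=30, noise_sd=0.002, seed=3, n_points=1200,
                        include_floor=True)
    return add_stickers(rec, toy_model, seed=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
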