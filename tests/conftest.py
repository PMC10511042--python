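import numpy as np
import pytest

from spheromet.synthetic import (MotionModel, RoundingKinetics,
                                 generate_nuclei_movie, generate_rounding_movie)


@pytest.fixture(scope="session")
def rounding_dataset():
    """3:1 rounding movie with the canonical 5 h / 18 h phase structure."""
    kin = RoundingKinetics(c_inf=0.95, t_latent=5.0, t_static=18.0)
    movie, truth = generate_rounding_movie(3.0, kin, frames=25, seed=11)
    return movie, truth


@pytest.fixture(scope="session")
def rounding_with_jump():
    kin = RoundingKinetics(c_inf=0.95, t_latent=5.0, t_static=18.0,
                           jumps=[(10.0, 0.15)])
    movie, truth = generate_rounding_movie(3.0, kin, frames=25, seed=12)
    return movie, truth


@pytest.fixture(scope="session")
def nuclei_dataset():
    """Small noisy nuclei movie for detection/tracking tests."""
    model = MotionModel(mode="independent_walk", n_cells=15, step_scale=1.0, seed=21)
    movie, truth = generate_nuclei_movie(model, shape=(20, 72, 72), frames=12, snr=5.0)
    return movie, truth


@pytest.fixture(scope="session")
def clean_nuclei_dataset():
    """Noise-free nuclei movie: localization oracle."""
    model = MotionModel(mode="independent_walk", n_cells=10, step_scale=1.0, seed=22)
    movie, truth = generate_nuclei_movie(model, shape=(20, 64, 64), frames=5,
                                         snr=np.inf)
    return movie, truth
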