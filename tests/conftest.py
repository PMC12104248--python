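import warnings

import numpy as np
import pytest

from pwlds import (
    EmissionCalibration,
    GroundTruthSpec,
    build_default_truth,
    calibrate_emissions,
    make_dataset,
)


@pytest.fixture(scope="session")
def truth():
    """Default three-mode ground-truth model (no emissions attached)."""
    return build_default_truth()


@pytest.fixture(scope="session")
def gaussian_emission(truth):
    cal = EmissionCalibration(n_observations=5, family="gaussian",
                              noise_variance=0.01)
    return calibrate_emissions(cal, truth, rng_seed=11)


@pytest.fixture(scope="session")
def gaussian_truth(gaussian_emission):
    """Ground truth with the calibrated 5-D Gaussian emission map."""
    return build_default_truth(emission=gaussian_emission)


@pytest.fixture(scope="session")
def gaussian_dataset(truth, gaussian_emission):
    """Reference 250-trial Gaussian dataset (5 dims, noise variance 0.01)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_dataset(truth, gaussian_emission, n_trials=250, rng_seed=7,
                            spec=GroundTruthSpec(),
                            calibration=EmissionCalibration())


@pytest.fixture(scope="session")
def small_poisson_dataset(truth):
    """Small Poisson dataset for unit tests (30 units, mean 2 spikes/bin)."""
    cal = EmissionCalibration(n_observations=30, family="poisson",
                              target_mean_rate=2.0)
    emission = calibrate_emissions(cal, truth, rng_seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_dataset(truth, emission, n_trials=80, rng_seed=6,
                            calibration=cal)
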