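import numpy as np
import pandas as pd
import pytest

from tundragreen import synthetic as syn


@pytest.fixture(scope="session")
def sites100():
    return syn.generate_sites(100, frac_greening=0.37, frac_browning=0.05, seed=1)


@pytest.fixture(scope="session")
def wide_sensor():
    """A single offset-free sensor active across the whole record."""
    return {"LX": syn.SensorModel("LX", ndvi_offset=0.0, radiometric_bound=0.05,
                                  active_years=(1984, 2016))}


@pytest.fixture(scope="session")
def dense_noiseless(sites100, wide_sensor):
    """Densely sampled, noise-free archive for 5 vegetated sites."""
    sub = sites100[~sites100["barren_flag"]].iloc[:5].reset_index(drop=True)
    obs, truth = syn.simulate_observations(
        sub, range(1985, 2017), sensors=wide_sensor,
        density_schedule=lambda y: 15, noise_sd=0.0, seed=11,
        interannual_sd=0.0, return_truth=True)
    return sub, obs, truth


@pytest.fixture(scope="session")
def dense_noisy(sites100, wide_sensor):
    """Densely sampled archive with realistic multiplicative noise."""
    sub = sites100[~sites100["barren_flag"]].iloc[:8].reset_index(drop=True)
    obs, truth = syn.simulate_observations(
        sub, range(1985, 2017), sensors=wide_sensor,
        density_schedule=lambda y: 12, noise_sd=0.02, seed=12,
        interannual_sd=0.0, return_truth=True)
    return sub, obs, truth
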