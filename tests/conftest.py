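import numpy as np
import pandas as pd
import pytest

from fbgeo.synth import SyntheticConfig, noiseless_config, simulate_survey


@pytest.fixture(scope="session")
def noiseless_survey():
    """Small survey with all qPCR noise, drift and failures off."""
    cfg = noiseless_config(SyntheticConfig(n_sites=60))
    sites, p16, p18, truth = simulate_survey(cfg, seed=42)
    return cfg, sites, p16, p18, truth


@pytest.fixture(scope="session")
def small_survey():
    """Default-noise survey at reduced size."""
    cfg = SyntheticConfig(n_sites=120)
    sites, p16, p18, truth = simulate_survey(cfg, seed=7)
    return cfg, sites, p16, p18, truth


@pytest.fixture(scope="session")
def uniform_sites_500():
    """Fixed irregular 500-site layout on a ~360 km square."""
    rng = np.random.default_rng(3)
    return rng.uniform(0.0, 360.0, (500, 2))


def make_samples(xy: np.ndarray, z: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"site_id": np.arange(len(z)), "x_km": xy[:, 0], "y_km": xy[:, 1], "value": z}
    )
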