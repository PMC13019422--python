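import warnings

import numpy as np
import pandas as pd
import pytest

import cloudphen
from cloudphen.config import RunConfig

warnings.filterwarnings("ignore", message=".*Perfect separation.*")
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="statsmodels")


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study shared across tests (default conditions,
    slightly smaller community for speed)."""
    cfg = RunConfig(seed=11)
    cfg.synth.n_species = 40
    data = cloudphen.simulate_study(cfg)
    data["config"] = cfg
    return data


@pytest.fixture(scope="session")
def study_populations(study):
    from cloudphen import phenology as phen
    pops = phen.population_phenology(study["captures"], study["visits"],
                                     study["config"].phenology)
    return pops


def make_rain(landscape="LX", days=None, rain=None, start="2015-01-01",
              daylight=12.0):
    """Minimal daily-rain frame for unit tests."""
    if rain is None:
        rain = np.zeros(days or 730)
    rain = np.asarray(rain, dtype=float)
    days = len(rain)
    dates = pd.date_range(start, periods=days, freq="D")
    return pd.DataFrame({
        "landscape": landscape, "date": dates, "rain_mm": rain,
        "daytime_rain_h": np.zeros(days), "daylight_h": daylight,
        "filled_flag": False,
    })


@pytest.fixture
def rain_factory():
    return make_rain
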