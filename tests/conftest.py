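import warnings

import numpy as np
import pandas as pd
import pytest

from tickburden.covariates import build_design
from tickburden.synthetic import SimConfig, generate_cohort, generate_environment

# statsmodels emits benign IRLS/domain warnings on extreme synthetic fits
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (306 deer, 7 years) plus its environment."""
    cfg = SimConfig(seed=11)
    env = generate_environment(cfg)
    hosts = generate_cohort(cfg, env)
    return cfg, env, hosts


@pytest.fixture(scope="session")
def default_design(default_cohort):
    cfg, (meteo, census), hosts = default_cohort
    return build_design(hosts, meteo, census)


@pytest.fixture()
def constant_meteo():
    """Gap-free daily series: constant 10 degC, 1 mm/day, one year."""
    dates = pd.date_range("2005-01-01", "2005-12-31", freq="D")
    return pd.DataFrame({"date": dates, "tmean": 10.0, "precip": 1.0})


def nb_frame(rng, n, beta0, beta1, theta, x_sd=1.0):
    """Single-covariate NB sample with log-linear mean, as a modelling frame."""
    x = rng.normal(0.0, x_sd, n)
    mu = np.exp(beta0 + beta1 * x)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame({"tick_count": y, "x": x})
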