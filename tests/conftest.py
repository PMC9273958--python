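import numpy as np
import pytest

from debibm import (ForcingConfig, default_deb_params, default_ibm_params,
                    integrate_lifecycle, synthesize_forcings)


@pytest.fixture(scope="session")
def deb_pars():
    return default_deb_params()


@pytest.fixture(scope="session")
def ibm_pars():
    return default_ibm_params()


@pytest.fixture(scope="session")
def lifecycle(deb_pars):
    """Reference life-cycle landmarks at f = 1, T_ref (adaptive solver)."""
    return integrate_lifecycle(deb_pars, f=1.0)


@pytest.fixture(scope="session")
def short_forcings():
    """Two years of noise-free synthetic forcings (fast deterministic runs)."""
    cfg = ForcingConfig(years=2, anomaly_sd_C=0.0, food_year_sd=0.0,
                        Z_F_year_sd=0.0, warming_slope_C_per_year=0.0)
    return synthesize_forcings(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
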