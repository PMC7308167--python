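"""Shared fixtures: parameter sets, constant forcing tables and the
packaged reference scenario run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sulfur_dynamics import load_site_parameters
from sulfur_dynamics.forcing import FORCING_COLUMNS
from sulfur_dynamics.integrator import run_simulation
from sulfur_dynamics.scenario import reference_scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exelberg():
    return load_site_parameters("exelberg")


@pytest.fixture(scope="session")
def jubilaeumswarte():
    return load_site_parameters("jubilaeumswarte")


def make_constant_forcing(n_days: int, start: str = "2010-01-01",
                          **overrides) -> pd.DataFrame:
    """Constant driver table: 8 deg C, theta on both moisture-response
    plateaus of the Exelberg set (resp = 1), no water fluxes, no
    deposition.  Columns are overridable with scalars or arrays."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    base = {
        "date": dates, "doy": dates.dayofyear,
        "precip": 0.0, "fog_precip": 0.0, "wet_dep": 0.0, "so2_air": 0.0,
        "infiltration": 0.0, "bypass": 0.0, "percolation": 0.0,
        "theta": 0.15, "soil_temp": 8.0, "wind_u2": 0.0,
        "kc_lai": 0.0, "kc_stress": 1.0, "doy_lc": 270, "doy_le": 300,
    }
    base.update(overrides)
    return pd.DataFrame(base, columns=FORCING_COLUMNS)


@pytest.fixture()
def constant_forcing():
    return make_constant_forcing


@pytest.fixture(scope="session")
def reference_run():
    """Full 1770-2100 run of the packaged scenario (Exelberg parameters,
    synthetic forcing, pre-industrial equilibrium initialization)."""
    forcing, params, init = reference_scenario()
    result = run_simulation(forcing, params, init)
    return forcing, result
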