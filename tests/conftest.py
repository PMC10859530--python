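"""Shared fixtures: everything is generated at test time, nothing on disk."""

import numpy as np
import pytest

from sorglt import cropmodel as cm
from sorglt import weathergen as wg
from sorglt.soilwater import SoilLayer, SoilProfile


@pytest.fixture()
def two_layer_profile():
    """Small uniform profile for hand-computable water-balance checks."""
    return SoilProfile(layers=[
        SoilLayer(thickness=300.0, ll15=0.10, dul=0.30, sat=0.40, kl=0.07, sw=0.10),
        SoilLayer(thickness=300.0, ll15=0.10, dul=0.30, sat=0.40, kl=0.07, sw=0.10),
    ])


@pytest.fixture(scope="session")
def belt_soil():
    return wg.make_soil("sandy loam", 150)


@pytest.fixture(scope="session")
def ww_weather():
    return wg.generate_season("WW", year_index=0, seed=11)


@pytest.fixture(scope="session")
def ed_weather():
    return wg.generate_season("ED", year_index=0, seed=11)


@pytest.fixture(scope="session")
def ed_season(belt_soil, ed_weather):
    """One completed drought season with the non-LT short cultivar."""
    return cm.run_season(ed_weather, belt_soil, cm.make_cultivar("short"),
                         cm.Management())


@pytest.fixture()
def constant_weather():
    """Flat benign weather: tt = 14 degC d/day, no rain shortage, no stress."""
    n = 365
    return wg.validate_weather(
        __import__("pandas").DataFrame({
            "year": np.full(n, 2001), "doy": np.arange(1, n + 1),
            "tmax": 30.0, "tmin": 20.0, "radn": 20.0, "rain": 6.0,
        }))
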