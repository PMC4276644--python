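import numpy as np
import pandas as pd
import pytest

from nearroad.config import DispersionConstants
from nearroad.dispersion import MetHour, derive_met
from nearroad.emissions import EFTable, SPEED_BINS, TEMP_BINS
from nearroad.network import Link, Receptor
from nearroad.reference import STABILITY_REGIMES, VEHICLE_CLASSES


def regime_met_hour(regime: str, wdir: float = 270.0, temp_f: float = 70.0) -> MetHour:
    """A MetHour built from one of the packaged representative regime rows."""
    return MetHour(
        timestamp=pd.Timestamp("2010-08-02 12:00"),
        **STABILITY_REGIMES[regime],
        wdir=wdir,
        temp_f=temp_f,
    )


@pytest.fixture(scope="session")
def constants() -> DispersionConstants:
    return DispersionConstants()


@pytest.fixture
def straight_link() -> Link:
    """A long straight north-south link through the origin."""
    return Link(
        id="main",
        nfc=11,
        aadt=100000.0,
        speed_by_period={"offpeak1": 55.0, "ampeak": 48.0,
                         "midday": 52.0, "pmpeak": 48.0},
        geometry=np.array([[0.0, -5000.0], [0.0, 5000.0]]),
    )


@pytest.fixture
def flat_ef_table() -> EFTable:
    """EF table with every entry 1.0 g/veh/mi (convexity/identity checks)."""
    values = np.ones((12, 1, len(VEHICLE_CLASSES), len(TEMP_BINS), len(SPEED_BINS)))
    return EFTable(("pm25",), VEHICLE_CLASSES, values)


def toy_two_level_table(diesel_ef: float = 0.3, gas_ef: float = 0.01) -> EFTable:
    """EF table where diesel classes share one level and gasoline another."""
    from nearroad.reference import DIESEL_CLASSES

    values = np.empty((12, 1, len(VEHICLE_CLASSES), len(TEMP_BINS), len(SPEED_BINS)))
    for ci, vc in enumerate(VEHICLE_CLASSES):
        values[:, 0, ci] = diesel_ef if vc in DIESEL_CLASSES else gas_ef
    return EFTable(("pm25",), VEHICLE_CLASSES, values)
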