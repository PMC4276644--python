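"""Packaged reference tables for a large urban U.S. road network.

Small printed tables that the rest of the package treats as fixtures:
the national-functional-class (NFC) roadway codes, the five modeled
time periods of day, the urban fleet-mix columns, and four
representative surface-meteorology hours spanning the stability
regimes observed in fall conditions.
"""

from __future__ import annotations

import pandas as pd

#: Urban NFC codes and descriptions.
NFC_CLASSES: dict[int, str] = {
    11: "Urban Interstate (Principal Arterial)",
    12: "Urban Other Freeway (Principal Arterial)",
    14: "Urban Other Principal Arterial",
    16: "Urban Minor Arterial",
    17: "Urban Collector",
    19: "Urban Local",
}

#: Eight vehicle classes (fuel, type) used by the emission-factor tables.
VEHICLE_CLASSES: tuple[str, ...] = (
    "LDGV", "LDGT1", "LDGT2", "HDGV", "MC", "LDDV", "LDDT", "HDDV",
)

#: Classes counted as diesel when summing a fleet's diesel percentage.
DIESEL_CLASSES: tuple[str, ...] = ("LDDV", "LDDT", "HDDV")

#: Fleet-mix columns for urban roadways (fractions of total fleet).
#: Keys are catalog names; the NFC groups they cover are listed alongside.
FLEET_MIX_FRACTIONS: dict[str, dict[str, float]] = {
    # NFC 11 (interstates, high diesel)
    "interstate": {
        "LDGV": 0.7082, "LDGT1": 0.1159, "LDGT2": 0.0590, "HDGV": 0.0221,
        "MC": 0.0040, "LDDV": 0.0098, "LDDT": 0.0051, "HDDV": 0.0769,
    },
    # NFC 12, 14, 16 (freeways and arterials, low diesel)
    "arterial": {
        "LDGV": 0.7566, "LDGT1": 0.1108, "LDGT2": 0.0564, "HDGV": 0.0220,
        "MC": 0.0020, "LDDV": 0.0104, "LDDT": 0.0049, "HDDV": 0.0370,
    },
    # NFC 17, 19 (collectors and locals)
    "other": {
        "LDGV": 0.5050, "LDGT1": 0.2498, "LDGT2": 0.1272, "HDGV": 0.0115,
        "MC": 0.0210, "LDDV": 0.0070, "LDDT": 0.0109, "HDDV": 0.0675,
    },
}

#: Default assignment of NFC code -> fleet-mix catalog name.
NFC_TO_MIX: dict[int, str] = {
    11: "interstate",
    12: "arterial", 14: "arterial", 16: "arterial",
    17: "other", 19: "other",
}

#: Modeled time periods of day: name -> (first hour, last hour), inclusive.
DEFAULT_PERIOD_SPANS: tuple[tuple[str, int, int], ...] = (
    ("offpeak1", 0, 6),
    ("ampeak", 7, 8),
    ("midday", 9, 15),
    ("pmpeak", 16, 18),
    ("offpeak2", 19, 23),
)

#: Representative hourly surface meteorology for the four stability regimes.
#: Columns: friction velocity u* (m/s), convective mixing height z_ic (m),
#: mechanical mixing height z_im (m), Monin-Obukhov length L (m),
#: roughness length z_0 (m), wind speed u (m/s).
STABILITY_REGIMES: dict[str, dict[str, float | None]] = {
    "convective": {"ustar": 0.229, "zic": 80.0, "zim": 252.0,
                   "L": -12.9, "z0": 0.167, "u": 1.65},
    "neutral": {"ustar": 0.734, "zic": 356.0, "zim": 1445.0,
                "L": -1223.7, "z0": 0.48, "u": 4.63},
    "stable": {"ustar": 0.254, "zic": None, "zim": 294.0,
               "L": 104.5, "z0": 0.104, "u": 2.66},
    "very_stable": {"ustar": 0.093, "zic": None, "zim": 137.0,
                    "L": 12.8, "z0": 0.104, "u": 1.03},
}

#: Grams per mile and seconds per hour, for g/mi/h -> g/m/s conversion.
METERS_PER_MILE = 1609.344
SECONDS_PER_HOUR = 3600.0


def fleet_mix_frame() -> pd.DataFrame:
    """Fleet-mix catalog as a tidy frame (mix_name, vehicle_class, fraction)."""
    rows = [
        {"mix_name": name, "vehicle_class": vc, "fraction": f}
        for name, fracs in FLEET_MIX_FRACTIONS.items()
        for vc, f in fracs.items()
    ]
    return pd.DataFrame(rows)


def stability_regime_frame() -> pd.DataFrame:
    """Representative meteorological conditions as a frame indexed by regime."""
    return pd.DataFrame(STABILITY_REGIMES).T.rename_axis("regime")
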