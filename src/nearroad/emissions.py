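"""Link-based mobile-source emissions.

Hourly emissions for link i are E_i = EF_i * A_i, where the composite
emission factor EF_i (g/vehicle/mile) is the fleet-mix-weighted sum of
class-specific emission factors looked up by pollutant, month,
temperature bin, and speed bin, and the activity A_i (vehicles) is
AADT_i scaled by hour-of-day, day-of-week, and month temporal
allocation factors. The line-source strength q (g/m/s) used to scale
unit-emission dispersion is e_per_mile / 1609.344 / 3600.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersion import MetHour
from .network import DEFAULT_PERIODS, Link, TimePeriodSet
from .reference import (
    DIESEL_CLASSES,
    FLEET_MIX_FRACTIONS,
    METERS_PER_MILE,
    SECONDS_PER_HOUR,
    VEHICLE_CLASSES,
)

__all__ = [
    "EFTable",
    "FleetMix",
    "TAFSet",
    "CompositeEF",
    "LinkEmission",
    "builtin_fleet_mixes",
    "lookup_ef",
    "composite_ef",
    "diesel_fraction",
    "hourly_activity",
    "link_emission_rate",
    "fleet_ratio",
    "compute_emissions",
]

#: Temperature bins, Fahrenheit.
TEMP_BINS = tuple(range(0, 101, 10))
#: Speed bins, miles/hour.
SPEED_BINS = (2.5,) + tuple(range(5, 76, 5))


def _nearest_bin(bins: np.ndarray, value: float) -> int:
    """Index of the nearest bin; exact midpoints round up; edges clamp."""
    i = int(np.searchsorted(bins, value))
    if i == 0:
        return 0
    if i == len(bins):
        return len(bins) - 1
    return i if value - bins[i - 1] >= bins[i] - value else i - 1


class EFTable:
    """Emission-factor lookup: (month, pollutant, vehicle class, temp bin,
    speed bin) -> grams/vehicle/mile.

    Key axes must be complete for every pollutant present; lookups snap
    to the nearest temperature and speed bins (ties round up).
    """

    def __init__(
        self,
        pollutants: tuple[str, ...],
        vclasses: tuple[str, ...],
        values: np.ndarray,
        temp_bins: tuple[float, ...] = TEMP_BINS,
        speed_bins: tuple[float, ...] = SPEED_BINS,
    ):
        self.pollutants = tuple(pollutants)
        self.vclasses = tuple(vclasses)
        self.temp_bins = np.asarray(temp_bins, dtype=float)
        self.speed_bins = np.asarray(speed_bins, dtype=float)
        values = np.asarray(values, dtype=float)
        expected = (
            12,
            len(self.pollutants),
            len(self.vclasses),
            len(self.temp_bins),
            len(self.speed_bins),
        )
        if values.shape != expected:
            raise ValueError(f"EF values must have shape {expected}, got {values.shape}")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("EF table must be complete with all ef >= 0")
        self.values = values
        self._p_index = {p: i for i, p in enumerate(self.pollutants)}
        self._c_index = {c: i for i, c in enumerate(self.vclasses)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EFTable":
        """Build from a long frame (month, pollutant, vclass, temp_bin,
        speed_bin, ef); missing axis combinations raise."""
        pollutants = tuple(sorted(df["pollutant"].unique()))
        vclasses = tuple(sorted(df["vclass"].unique()))
        temp_bins = tuple(sorted(df["temp_bin"].unique()))
        speed_bins = tuple(sorted(df["speed_bin"].unique()))
        shaped = (
            df.set_index(["month", "pollutant", "vclass", "temp_bin", "speed_bin"])["ef"]
            .reindex(
                pd.MultiIndex.from_product(
                    [range(1, 13), pollutants, vclasses, temp_bins, speed_bins]
                )
            )
            .to_numpy()
            .reshape(12, len(pollutants), len(vclasses), len(temp_bins), len(speed_bins))
        )
        if np.any(np.isnan(shaped)):
            raise ValueError("EF table has missing (month,pollutant,vclass,temp,speed) keys")
        return cls(pollutants, vclasses, shaped, temp_bins, speed_bins)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [range(1, 13), self.pollutants, self.vclasses, self.temp_bins, self.speed_bins],
            names=["month", "pollutant", "vclass", "temp_bin", "speed_bin"],
        )
        return pd.Series(self.values.ravel(), index=idx, name="ef").reset_index()

    def lookup(
        self, pollutant: str, vclass: str, month: int, temp_f: float, speed_mph: float
    ) -> float:
        if not 1 <= int(month) <= 12:
            raise ValueError(f"month must be in 1..12, got {month}")
        try:
            pi = self._p_index[pollutant]
            ci = self._c_index[vclass]
        except KeyError as exc:
            raise KeyError(f"EF table has no axis entry for {exc.args[0]!r}") from None
        ti = _nearest_bin(self.temp_bins, temp_f)
        si = _nearest_bin(self.speed_bins, speed_mph)
        return float(self.values[int(month) - 1, pi, ci, ti, si])


def lookup_ef(
    table: EFTable, pollutant: str, vclass: str, month: int, temp_f: float, speed_mph: float
) -> float:
    """Class-specific EF (g/veh/mi) at the nearest temperature/speed bins."""
    return table.lookup(pollutant, vclass, month, temp_f, speed_mph)


@dataclass
class FleetMix:
    """Fractional composition of traffic over the eight vehicle classes."""

    name: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(VEHICLE_CLASSES)
        if unknown:
            raise ValueError(f"fleet mix {self.name!r}: unknown classes {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError(f"fleet mix {self.name!r}: fractions must be >= 0")
        total = sum(self.fractions.values())
        if not 0.995 <= total <= 1.005:
            raise ValueError(
                f"fleet mix {self.name!r}: fractions sum to {total:.4f}, expected ~1"
            )


def builtin_fleet_mixes() -> dict[str, FleetMix]:
    """The packaged urban fleet-mix catalog (interstate/arterial/other)."""
    return {
        name: FleetMix(name, dict(fracs)) for name, fracs in FLEET_MIX_FRACTIONS.items()
    }


def diesel_fraction(mix: FleetMix) -> float:
    """Diesel percent of the fleet: 100 x (HDDV + LDDT + LDDV fractions).

    Uses the raw (unrenormalized) printed fractions so catalog columns
    reproduce their stated diesel percentages exactly.
    """
    return 100.0 * sum(mix.fractions.get(cls, 0.0) for cls in DIESEL_CLASSES)


@dataclass(frozen=True)
class CompositeEF:
    """Fleet-weighted emission factor with its lookup provenance."""

    value: float  # g/vehicle/mile
    mix_name: str
    pollutant: str
    month: int
    temp_bin: float
    speed_bin: float


def composite_ef(
    table: EFTable,
    mix: FleetMix,
    pollutant: str,
    month: int,
    temp_f: float,
    speed_mph: float,
) -> CompositeEF:
    """EF_i: fraction-weighted sum of class EFs, fractions renormalized to 1."""
    if not mix.fractions:
        raise ValueError("fleet mix has no classes")
    total = sum(mix.fractions.values())
    value = sum(
        (f / total) * table.lookup(pollutant, vc, month, temp_f, speed_mph)
        for vc, f in mix.fractions.items()
        if f > 0
    )
    ti = _nearest_bin(table.temp_bins, temp_f)
    si = _nearest_bin(table.speed_bins, speed_mph)
    return CompositeEF(
        value=float(value),
        mix_name=mix.name,
        pollutant=pollutant,
        month=int(month),
        temp_bin=float(table.temp_bins[ti]),
        speed_bin=float(table.speed_bins[si]),
    )


@dataclass
class TAFSet:
    """Temporal allocation factors turning AADT into hourly volumes.

    hourly[(daytype, hour)] with daytype in {"weekday", "weekend"} sums
    to 1 over the 24 hours of each daytype; day-of-week (Mon=0) and
    month factors each average to 1, so AADT stays the annual-average
    daily total.
    """

    hourly: dict[tuple[str, int], float]
    dow: dict[int, float]
    month: dict[int, float]

    def __post_init__(self) -> None:
        for daytype in ("weekday", "weekend"):
            hours = [self.hourly.get((daytype, h)) for h in range(24)]
            if any(v is None for v in hours):
                raise ValueError(f"hourly TAFs incomplete for daytype {daytype!r}")
            if abs(sum(hours) - 1.0) > 1e-9:
                raise ValueError(f"hourly TAFs for {daytype!r} must sum to 1")
        if sorted(self.dow) != list(range(7)):
            raise ValueError("dow TAFs must cover Monday(0)..Sunday(6)")
        if abs(np.mean(list(self.dow.values())) - 1.0) > 1e-9:
            raise ValueError("dow TAFs must average to 1")
        if sorted(self.month) != list(range(1, 13)):
            raise ValueError("month TAFs must cover months 1..12")
        if abs(np.mean(list(self.month.values())) - 1.0) > 1e-9:
            raise ValueError("month TAFs must average to 1")

    def factor(self, timestamp: pd.Timestamp) -> float:
        ts = pd.Timestamp(timestamp)
        daytype = "weekend" if ts.dayofweek >= 5 else "weekday"
        return (
            self.hourly[(daytype, ts.hour)]
            * self.dow[ts.dayofweek]
            * self.month[ts.month]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "hourly", "key": daytype, "subkey": h, "factor": f}
            for (daytype, h), f in sorted(self.hourly.items())
        ]
        rows += [
            {"kind": "dow", "key": str(d), "subkey": -1, "factor": f}
            for d, f in sorted(self.dow.items())
        ]
        rows += [
            {"kind": "month", "key": str(m), "subkey": -1, "factor": f}
            for m, f in sorted(self.month.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TAFSet":
        hourly = {
            (r.key, int(r.subkey)): float(r.factor)
            for r in df[df["kind"] == "hourly"].itertuples()
        }
        dow = {int(r.key): float(r.factor) for r in df[df["kind"] == "dow"].itertuples()}
        month = {
            int(r.key): float(r.factor) for r in df[df["kind"] == "month"].itertuples()
        }
        return cls(hourly=hourly, dow=dow, month=month)


def hourly_activity(aadt: float, tafs: TAFSet, timestamp) -> float:
    """A_i: vehicles in the hour, AADT scaled by the three TAF factors."""
    return aadt * tafs.factor(pd.Timestamp(timestamp))


@dataclass(frozen=True)
class LinkEmission:
    """Hourly emission for one link: g/mile over the hour and g/m/s."""

    link_id: str
    timestamp: pd.Timestamp
    pollutant: str
    e_per_mile: float
    q: float
    valid: bool = True


def link_emission_rate(
    link: Link,
    table: EFTable,
    mix: FleetMix,
    tafs: TAFSet,
    met_hour: MetHour,
    pollutant: str,
    periods: TimePeriodSet = DEFAULT_PERIODS,
) -> LinkEmission:
    """E_i = EF_i x A_i for one link-hour, plus the line strength q.

    Hours whose meteorology lacks a temperature are flagged invalid
    rather than silently assigned an emission.
    """
    ts = pd.Timestamp(met_hour.timestamp)
    if met_hour.temp_f is None or not np.isfinite(met_hour.temp_f):
        return LinkEmission(link.id, ts, pollutant, float("nan"), float("nan"), valid=False)
    speed = link.speed_for(periods.period_of(ts.hour))
    ef = composite_ef(table, mix, pollutant, ts.month, met_hour.temp_f, speed)
    activity = hourly_activity(link.aadt, tafs, ts)
    e_per_mile = ef.value * activity
    q = e_per_mile / METERS_PER_MILE / SECONDS_PER_HOUR
    return LinkEmission(link.id, ts, pollutant, e_per_mile, q)


def fleet_ratio(
    table: EFTable,
    mix_a: FleetMix,
    mix_b: FleetMix,
    pollutant: str,
    month: int,
    temp_f: float,
    speed_mph: float,
) -> float:
    """Ratio of composite EFs for two fleets at matched conditions.

    All non-fleet factors (hour, day, month weighting) cancel, so this
    isolates the fleet-composition sensitivity of a pollutant.
    """
    a = composite_ef(table, mix_a, pollutant, month, temp_f, speed_mph).value
    b = composite_ef(table, mix_b, pollutant, month, temp_f, speed_mph).value
    if b == 0:
        raise ZeroDivisionError("denominator fleet has zero composite EF")
    return a / b


def compute_emissions(
    links: list[Link],
    table: EFTable,
    mixes: dict[str, FleetMix],
    tafs: TAFSet,
    met_series: list[MetHour],
    pollutants: list[str],
    periods: TimePeriodSet = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Hourly emissions for every link and pollutant over a met series.

    Returns a long frame (link_id, timestamp, pollutant, e_per_mile, q,
    valid); each link uses the fleet mix its `mix_name`/NFC resolves to.
    """
    rows = []
    for link in links:
        mix = mixes[link.resolved_mix_name()]
        for m in met_series:
            for pollutant in pollutants:
                em = link_emission_rate(link, table, mix, tafs, m, pollutant, periods)
                rows.append(
                    (em.link_id, em.timestamp, em.pollutant, em.e_per_mile, em.q, em.valid)
                )
    return pd.DataFrame(
        rows, columns=["link_id", "timestamp", "pollutant", "e_per_mile", "q", "valid"]
    )
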