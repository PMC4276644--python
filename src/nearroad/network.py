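"""Road links, receptors, traffic-recorder records, and geometry operations.

Coordinates are projected meters throughout; the engine never does geodesy.
Links are polylines with uniform traffic attributes: NFC roadway class,
annual-average daily traffic (AADT), and one speed per modeled time period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .reference import DEFAULT_PERIOD_SPANS, NFC_CLASSES, NFC_TO_MIX

__all__ = [
    "Link",
    "Receptor",
    "PTRRecord",
    "TimePeriodSet",
    "DEFAULT_PERIODS",
    "UPWIND",
    "perpendicular_distance",
    "effective_distance",
]

#: Sentinel returned by effective_distance when the receptor is upwind.
UPWIND = None


@dataclass(eq=False)
class Link:
    """A road segment: polyline geometry plus uniform traffic attributes.

    Parameters
    ----------
    id : str
        Link identifier.
    nfc : int
        National functional class, one of the urban codes (11..19).
    aadt : float
        Annual-average daily traffic, vehicles/day.
    speed_by_period : dict
        Time-period name -> speed in miles/hour. If only one of the two
        off-peak periods is present the other is filled from it.
    geometry : (n, 2) array
        Polyline vertices in projected meters, n >= 2.
    mix_name : str, optional
        Fleet-mix catalog name; defaults by NFC when unset.
    diesel_group : {"HD", "LD"}, optional
        High-/low-diesel designation; defaults to HD for NFC 11 and LD for
        NFC 12. Measurement-driven reassignment may override it.
    """

    id: str
    nfc: int
    aadt: float
    speed_by_period: dict[str, float]
    geometry: np.ndarray
    mix_name: str | None = None
    diesel_group: str | None = None

    def __post_init__(self) -> None:
        if self.nfc not in NFC_CLASSES:
            raise ValueError(
                f"link {self.id!r}: unknown NFC class {self.nfc}; "
                f"expected one of {sorted(NFC_CLASSES)}"
            )
        if not self.aadt >= 0:
            raise ValueError(f"link {self.id!r}: aadt must be >= 0")
        speeds = dict(self.speed_by_period)
        if "offpeak1" in speeds and "offpeak2" not in speeds:
            speeds["offpeak2"] = speeds["offpeak1"]
        if "offpeak2" in speeds and "offpeak1" not in speeds:
            speeds["offpeak1"] = speeds["offpeak2"]
        for name, s in speeds.items():
            if not s > 0:
                raise ValueError(f"link {self.id!r}: speed for {name!r} must be > 0")
        self.speed_by_period = speeds
        geom = np.asarray(self.geometry, dtype=float)
        if geom.ndim != 2 or geom.shape[1] != 2 or geom.shape[0] < 2:
            raise ValueError(f"link {self.id!r}: geometry must be an (n>=2, 2) array")
        self.geometry = geom
        if not self.length > 0:
            raise ValueError(f"link {self.id!r}: degenerate zero-length geometry")

    @property
    def length(self) -> float:
        """Polyline length in meters."""
        return float(np.hypot(*np.diff(self.geometry, axis=0).T).sum())

    @property
    def line(self) -> LineString:
        return LineString(self.geometry)

    def speed_for(self, period: str) -> float:
        try:
            return self.speed_by_period[period]
        except KeyError:
            raise KeyError(
                f"link {self.id!r} has no speed for period {period!r}"
            ) from None

    def resolved_mix_name(self) -> str:
        """The fleet-mix catalog name in force (explicit or NFC default)."""
        return self.mix_name if self.mix_name is not None else NFC_TO_MIX[self.nfc]

    def resolved_diesel_group(self) -> str | None:
        """HD/LD designation (explicit, else NFC 11 -> HD, NFC 12 -> LD)."""
        if self.diesel_group is not None:
            return self.diesel_group
        return {11: "HD", 12: "LD"}.get(self.nfc)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Link):
            return NotImplemented
        return (
            self.id == other.id
            and self.nfc == other.nfc
            and math.isclose(self.aadt, other.aadt, rel_tol=1e-12, abs_tol=1e-9)
            and self.speed_by_period.keys() == other.speed_by_period.keys()
            and all(
                math.isclose(v, other.speed_by_period[k], rel_tol=1e-12, abs_tol=1e-9)
                for k, v in self.speed_by_period.items()
            )
            and self.geometry.shape == other.geometry.shape
            and np.allclose(self.geometry, other.geometry, rtol=1e-12, atol=1e-6)
            and self.mix_name == other.mix_name
            and self.diesel_group == other.diesel_group
        )


@dataclass
class Receptor:
    """A concentration receptor (e.g. a participant's home location)."""

    id: str
    x: float
    y: float
    height: float = 1.5
    group_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.height >= 0:
            raise ValueError(f"receptor {self.id!r}: height must be >= 0")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class PTRRecord:
    """One permanent-traffic-recorder measurement for a link and year."""

    link_id: str
    year: int
    measured_aadt: float
    measured_caadt: float | None = None

    def __post_init__(self) -> None:
        if not self.measured_aadt >= 0:
            raise ValueError("measured_aadt must be >= 0")
        if self.measured_caadt is not None and not (
            0 <= self.measured_caadt <= self.measured_aadt
        ):
            raise ValueError(
                f"PTR {self.link_id!r}/{self.year}: measured_caadt must lie in "
                "[0, measured_aadt]"
            )


class TimePeriodSet:
    """An ordered partition of the 24 hours of day into named periods."""

    def __init__(self, spans: tuple[tuple[str, int, int], ...] = DEFAULT_PERIOD_SPANS):
        covered: dict[int, str] = {}
        for name, start, end in spans:
            if not (0 <= start <= end <= 23):
                raise ValueError(f"period {name!r}: bad hour span {start}-{end}")
            for h in range(start, end + 1):
                if h in covered:
                    raise ValueError(f"hour {h} covered by both {covered[h]!r} and {name!r}")
                covered[h] = name
        if len(covered) != 24:
            missing = sorted(set(range(24)) - set(covered))
            raise ValueError(f"periods do not cover hours {missing}")
        self.spans = tuple((str(n), int(s), int(e)) for n, s, e in spans)
        self._by_hour = covered

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.spans)

    def period_of(self, hour: int) -> str:
        return self._by_hour[int(hour)]

    def hours(self, name: str) -> list[int]:
        return [h for h, n in self._by_hour.items() if n == name]

    def n_hours(self, name: str) -> int:
        return len(self.hours(name))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TimePeriodSet) and self.spans == other.spans

    def __repr__(self) -> str:
        return f"TimePeriodSet({self.spans!r})"


DEFAULT_PERIODS = TimePeriodSet()


def perpendicular_distance(link: Link, point: tuple[float, float]) -> float:
    """Euclidean distance from a point to the nearest point on the polyline.

    Segment-clamped: points beyond a link's end measure to the endpoint,
    not to the infinite line through it.
    """
    return float(link.line.distance(Point(point)))


def transport_unit_vector(wind_from_deg: float) -> np.ndarray:
    """Unit (east, north) vector of downwind transport.

    Wind direction is degrees clockwise from north, the direction the wind
    blows FROM; transport is toward wind_from + 180.
    """
    b = math.radians((wind_from_deg + 180.0) % 360.0)
    return np.array([math.sin(b), math.cos(b)])


def effective_distance(
    link: Link,
    receptor: Receptor,
    wind_from_deg: float,
    cos_cap: float = 0.1,
) -> float | None:
    """Source-receptor separation along the hourly transport direction.

    d_eff = d_perp / cos(theta) where theta is the angle between the
    downwind transport direction and the road normal pointing toward the
    receptor. Returns :data:`UPWIND` (None) when cos(theta) <= cos_cap,
    i.e. the receptor is effectively upwind; otherwise d_eff <= d_perp/cos_cap.
    """
    if not 0.0 <= wind_from_deg < 360.0:
        raise ValueError("wind_from_deg must lie in [0, 360)")
    line = link.line
    pt = receptor.point
    d_perp = float(line.distance(pt))
    if d_perp == 0.0:
        return 0.0
    nearest = line.interpolate(line.project(pt))
    normal = np.array([pt.x - nearest.x, pt.y - nearest.y]) / d_perp
    cos_theta = float(transport_unit_vector(wind_from_deg) @ normal)
    if cos_theta <= cos_cap:
        return UPWIND
    return d_perp / cos_theta
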