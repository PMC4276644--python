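"""Readers and writers for every file format the pipeline exchanges.

Links travel as GeoJSON LineString features or CSV with a WKT geometry
column; meteorology as a plain CSV or an AERMET-style surface-file
subset; receptors, traffic-recorder records, emissions, unit
concentrations, and summaries as CSV. All readers validate and reject
malformed records rather than silently coercing them, and every
writer/reader pair round-trips.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString, mapping, shape

from .dispersion import ChiMatrix, MetHour
from .network import Link, PTRRecord, Receptor

__all__ = [
    "read_links",
    "write_links",
    "read_receptors",
    "write_receptors",
    "read_ptr",
    "write_ptr",
    "read_met",
    "write_met",
    "write_sfc",
    "read_chi",
    "write_chi",
]

_SPEED_PREFIX = "speed_"
#: Sentinel for missing values in the AERMET-style surface file subset.
_SFC_MISSING = -99900.0


def _check_projected(coords: np.ndarray, path) -> None:
    if np.all(np.abs(coords[:, 0]) <= 180.0) and np.all(np.abs(coords[:, 1]) <= 90.0):
        raise ValueError(
            f"{path}: coordinates look geographic (degrees); reproject the "
            "geometry to a projected CRS in meters before loading"
        )


def _link_from_props(props: dict, geom: np.ndarray, path) -> Link:
    speeds = {
        k[len(_SPEED_PREFIX):]: float(v)
        for k, v in props.items()
        if k.startswith(_SPEED_PREFIX) and v is not None and not _isnan(v)
    }
    mix = props.get("mix_name")
    group = props.get("diesel_group")
    return Link(
        id=str(props["id"]),
        nfc=int(props["nfc"]),
        aadt=float(props["aadt"]),
        speed_by_period=speeds,
        geometry=geom,
        mix_name=None if mix in (None, "") or _isnan(mix) else str(mix),
        diesel_group=None if group in (None, "") or _isnan(group) else str(group),
    )


def _isnan(v) -> bool:
    return isinstance(v, float) and math.isnan(v)


def read_links(path: str | Path, format: str | None = None) -> list[Link]:
    """Read links from GeoJSON or CSV-with-WKT (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    links: list[Link] = []
    if fmt == "geojson":
        doc = json.loads(path.read_text())
        for feat in doc["features"]:
            geom = shape(feat["geometry"])
            if not isinstance(geom, LineString):
                raise ValueError(f"{path}: link geometry must be LineString")
            coords = np.asarray(geom.coords, dtype=float)
            _check_projected(coords, path)
            links.append(_link_from_props(feat["properties"], coords, path))
    elif fmt == "csv":
        df = pd.read_csv(path)
        for row in df.to_dict("records"):
            geom = shapely_wkt.loads(row.pop("geometry"))
            coords = np.asarray(geom.coords, dtype=float)
            _check_projected(coords, path)
            links.append(_link_from_props(row, coords, path))
    else:
        raise ValueError(f"unknown link format {fmt!r}")
    return links


def _link_props(link: Link) -> dict:
    props: dict = {"id": link.id, "nfc": link.nfc, "aadt": link.aadt}
    for period, speed in sorted(link.speed_by_period.items()):
        props[f"{_SPEED_PREFIX}{period}"] = speed
    if link.mix_name is not None:
        props["mix_name"] = link.mix_name
    if link.diesel_group is not None:
        props["diesel_group"] = link.diesel_group
    return props


def write_links(links: list[Link], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    if fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": _link_props(l),
                    "geometry": mapping(LineString(l.geometry)),
                }
                for l in links
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif fmt == "csv":
        rows = []
        for l in links:
            row = _link_props(l)
            row["geometry"] = LineString(l.geometry).wkt
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown link format {fmt!r}")


def read_receptors(path: str | Path) -> list[Receptor]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        out.append(
            Receptor(
                id=str(row.id),
                x=float(row.x),
                y=float(row.y),
                height=float(getattr(row, "height", 1.5)),
                group_label=str(getattr(row, "group_label", "unassigned")),
            )
        )
    return out


def write_receptors(receptors: list[Receptor], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": r.id, "x": r.x, "y": r.y, "height": r.height,
             "group_label": r.group_label}
            for r in receptors
        ]
    ).to_csv(path, index=False)


def read_ptr(path: str | Path) -> list[PTRRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        caadt = getattr(row, "measured_caadt", None)
        out.append(
            PTRRecord(
                link_id=str(row.link_id),
                year=int(row.year),
                measured_aadt=float(row.measured_aadt),
                measured_caadt=None if caadt is None or pd.isna(caadt) else float(caadt),
            )
        )
    return out


def write_ptr(records: list[PTRRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "link_id": r.link_id,
                "year": r.year,
                "measured_aadt": r.measured_aadt,
                "measured_caadt": np.nan if r.measured_caadt is None else r.measured_caadt,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


_MET_FIELDS = ("ustar", "L", "zic", "zim", "z0", "u", "wdir", "temp_f")
#: Fields that must be present for an hour to be complete (zic only when L<0).
_MET_REQUIRED = ("ustar", "L", "zim", "z0", "u", "wdir", "temp_f")


def _met_hour_from_values(ts: pd.Timestamp, vals: dict[str, float]) -> MetHour:
    clean = {
        k: (None if v is None or not math.isfinite(v) else float(v))
        for k, v in vals.items()
    }
    complete = all(clean.get(k) is not None for k in _MET_REQUIRED)
    if complete and clean["L"] is not None and clean["L"] < 0 and clean.get("zic") is None:
        complete = False
    if complete and (
        clean["ustar"] <= 0 or clean["zim"] <= 0 or clean["z0"] <= 0
        or clean["u"] < 0 or clean["L"] == 0
    ):
        complete = False
    if not complete:
        return MetHour(timestamp=ts, complete=False, **clean)
    return MetHour(timestamp=ts, complete=True, **clean)


def read_met(path: str | Path, format: str | None = None) -> list[MetHour]:
    """Read an hourly meteorology series (CSV or AERMET-style SFC subset).

    Hours missing any required field are flagged incomplete, never
    dropped; duplicate timestamps are an error.
    """
    path = Path(path)
    fmt = format or ("sfc" if path.suffix.lower() == ".sfc" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, parse_dates=["timestamp"])
    elif fmt == "sfc":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            names=["year", "month", "day", "hour"] + list(_MET_FIELDS),
            comment="#",
        )
        df = df.replace(_SFC_MISSING, np.nan)
        df["timestamp"] = pd.to_datetime(df[["year", "month", "day", "hour"]])
    else:
        raise ValueError(f"unknown met format {fmt!r}")
    ts = pd.DatetimeIndex(df["timestamp"])
    if ts.duplicated().any():
        dupes = ts[ts.duplicated()].unique()
        raise ValueError(f"{path}: duplicate timestamps {list(dupes[:3])}")
    out = []
    for _, row in df.iterrows():
        vals = {k: (row[k] if k in row and pd.notna(row[k]) else None) for k in _MET_FIELDS}
        out.append(_met_hour_from_values(pd.Timestamp(row["timestamp"]), vals))
    return out


def met_to_frame(series: list[MetHour]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"timestamp": m.timestamp,
             **{k: (np.nan if getattr(m, k) is None else getattr(m, k))
                for k in _MET_FIELDS}}
            for m in series
        ]
    )


def write_met(series: list[MetHour], path: str | Path) -> None:
    met_to_frame(series).to_csv(path, index=False)


def write_sfc(series: list[MetHour], path: str | Path) -> None:
    """Write the AERMET-style surface-file subset twin of a met series."""
    lines = ["# year month day hour " + " ".join(_MET_FIELDS)]
    for m in series:
        vals = [
            _SFC_MISSING if getattr(m, k) is None else float(getattr(m, k))
            for k in _MET_FIELDS
        ]
        ts = m.timestamp
        lines.append(
            f"{ts.year:4d} {ts.month:2d} {ts.day:2d} {ts.hour:2d} "
            + " ".join(f"{v:12.4f}" for v in vals)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_chi(chi: ChiMatrix, path: str | Path) -> None:
    """Loss-free long CSV (link_id, receptor_id, timestamp, chi)."""
    chi.to_long_frame().to_csv(path, index=False)


def read_chi(path: str | Path) -> ChiMatrix:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    link_ids = list(pd.unique(df["link_id"].astype(str)))
    receptor_ids = list(pd.unique(df["receptor_id"].astype(str)))
    timestamps = pd.DatetimeIndex(pd.unique(df["timestamp"]))
    values = (
        df.assign(link_id=df["link_id"].astype(str), receptor_id=df["receptor_id"].astype(str))
        .set_index(["link_id", "receptor_id", "timestamp"])["chi"]
        .reindex(pd.MultiIndex.from_product([link_ids, receptor_ids, timestamps]))
        .to_numpy()
        .reshape(len(link_ids), len(receptor_ids), len(timestamps))
    )
    valid = ~np.all(np.isnan(values), axis=(0, 1))
    return ChiMatrix(link_ids, receptor_ids, timestamps, values, valid)
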