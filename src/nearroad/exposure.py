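"""Receptor concentrations, completeness-filtered summaries, and cohorts.

The concentration at a receptor is the emissions-weighted sum of unit
concentrations over links, C = sum_i q_i * chi_i. Hour validity (calm or
incomplete meteorology) and a 75% completeness rule per day-period cell
govern which values enter exposure statistics. Receptors are classified
into high-traffic high-diesel (HTHD), high-traffic low-diesel (HTLD),
and low-traffic (LT) cohorts by proximity to designated roadways.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ExposureConstants
from .dispersion import ChiMatrix, MetHour
from .network import (
    DEFAULT_PERIODS,
    Link,
    Receptor,
    TimePeriodSet,
    effective_distance,
    perpendicular_distance,
)

__all__ = [
    "hour_valid",
    "combine",
    "period_average",
    "summarize_periods",
    "classify_receptors",
    "distance_decay_profile",
]


def hour_valid(m: MetHour, min_wind_speed: float = 0.5) -> bool:
    """Valid iff the record is complete and wind speed >= 0.5 m/s (inclusive)."""
    return bool(m.complete and m.u is not None and m.u >= min_wind_speed)


def combine(chi: ChiMatrix, emissions: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """C = sum_i q_i * chi_i per receptor-hour.

    `emissions` is the long frame from :func:`nearroad.emissions.compute_emissions`
    with q in g/m/s; chi is per (g/m/s). Hours masked in chi, or with an
    invalid emission, come out invalid with no concentration value.

    Returns a long frame (receptor_id, timestamp, pollutant, c, valid).
    """
    em = emissions[emissions["pollutant"] == pollutant]
    extra = set(em["link_id"].unique()) - set(chi.link_ids)
    if extra:
        raise ValueError(f"emissions reference links absent from chi: {sorted(extra)}")
    # (n_links, n_hours) aligned to the chi matrix axes
    q = (
        em.pivot_table(index="link_id", columns="timestamp", values="q", aggfunc="first")
        .reindex(index=chi.link_ids, columns=chi.timestamps)
        .to_numpy()
    )
    em_valid = (
        em.pivot_table(
            index="link_id", columns="timestamp", values="valid", aggfunc="first"
        )
        .reindex(index=chi.link_ids, columns=chi.timestamps)
        .to_numpy()
    )
    hour_ok = chi.valid & ~np.any(
        np.isnan(q) | (em_valid == False), axis=0  # noqa: E712
    )
    conc = np.einsum("lt,lrt->rt", np.nan_to_num(q), np.nan_to_num(chi.values))
    conc[:, ~hour_ok] = np.nan
    n_r, n_t = conc.shape
    return pd.DataFrame(
        {
            "receptor_id": np.repeat(np.asarray(chi.receptor_ids, dtype=object), n_t),
            "timestamp": np.tile(chi.timestamps, n_r),
            "pollutant": pollutant,
            "c": conc.ravel(),
            "valid": np.tile(hour_ok, n_r),
        }
    )


def period_average(
    series: pd.DataFrame,
    periods: TimePeriodSet = DEFAULT_PERIODS,
    completeness: float = 0.75,
) -> pd.DataFrame:
    """Per-day, per-period mean concentrations under a completeness rule.

    A day x period cell is reported iff valid_hours/period_hours >=
    completeness (inclusive); its value is the mean of the valid hourly
    concentrations. A "daily" row applies the same rule over all 24 h.

    Returns (receptor_id, date, period, c_mean, n_valid, n_hours, reported).
    """
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must lie in (0, 1]")
    df = series.copy()
    ts = pd.DatetimeIndex(df["timestamp"])
    df["date"] = ts.normalize()
    df["period"] = [periods.period_of(h) for h in ts.hour]
    frames = []
    for label, group_cols in (("period", ["receptor_id", "date", "period"]),
                              ("daily", ["receptor_id", "date"])):
        g = df.groupby(group_cols, observed=True)
        out = g.agg(
            c_sum=("c", lambda s: np.nansum(s.to_numpy())),
            n_valid=("valid", "sum"),
            n_hours=("valid", "size"),
        ).reset_index()
        if label == "daily":
            out["period"] = "daily"
            out["n_hours"] = 24
        else:
            out["n_hours"] = [periods.n_hours(p) for p in out["period"]]
        out["reported"] = out["n_valid"] / out["n_hours"] >= completeness
        with np.errstate(invalid="ignore"):
            out["c_mean"] = np.where(
                out["reported"] & (out["n_valid"] > 0),
                out["c_sum"] / out["n_valid"],
                np.nan,
            )
        frames.append(out.drop(columns="c_sum"))
    cols = ["receptor_id", "date", "period", "c_mean", "n_valid", "n_hours", "reported"]
    return pd.concat(frames, ignore_index=True)[cols]


def summarize_periods(cells: pd.DataFrame, by: str = "receptor_id") -> pd.DataFrame:
    """Distribution stats of reported cell means, per group and period.

    Returns (group, period, min, p5, median, mean, p95, max, n); the
    ordering min <= p5 <= median <= p95 <= max holds by construction.
    """
    reported = cells[cells["reported"] & cells["c_mean"].notna()]
    rows = []
    for (group, period), sub in reported.groupby([by, "period"], observed=True):
        v = sub["c_mean"].to_numpy()
        rows.append(
            {
                by: group,
                "period": period,
                "min": v.min(),
                "p5": np.percentile(v, 5),
                "median": np.median(v),
                "mean": v.mean(),
                "p95": np.percentile(v, 95),
                "max": v.max(),
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)


def classify_receptors(
    receptors: list[Receptor],
    links: list[Link],
    ht_aadt_min: float = 50000.0,
    near_m: float = 300.0,
    verynear_m: float = 150.0,
) -> pd.DataFrame:
    """Cohort labels by proximity to high-traffic HD/LD roadways.

    HTHD if within near_m of any high-traffic high-diesel link (HD takes
    precedence), else HTLD if within near_m of any high-traffic low-diesel
    link, else LT. High traffic means AADT >= ht_aadt_min. Also records
    the within-verynear_m flag and the nearest high-traffic link.

    Returns (receptor_id, label, nearest_ht_link, nearest_ht_m, within_verynear).
    """
    ht = {
        "HD": [l for l in links if l.aadt >= ht_aadt_min and l.resolved_diesel_group() == "HD"],
        "LD": [l for l in links if l.aadt >= ht_aadt_min and l.resolved_diesel_group() == "LD"],
    }
    rows = []
    for rec in receptors:
        dists = {
            grp: min(
                ((perpendicular_distance(l, (rec.x, rec.y)), l.id) for l in ls),
                default=(np.inf, None),
            )
            for grp, ls in ht.items()
        }
        if dists["HD"][0] <= near_m:
            label = "HTHD"
        elif dists["LD"][0] <= near_m:
            label = "HTLD"
        else:
            label = "LT"
        nearest = min(dists.values())
        rows.append(
            {
                "receptor_id": rec.id,
                "label": label,
                "nearest_ht_link": nearest[1],
                "nearest_ht_m": nearest[0] if np.isfinite(nearest[0]) else np.nan,
                "within_verynear": bool(nearest[0] <= verynear_m),
            }
        )
    return pd.DataFrame(rows)


def distance_decay_profile(
    concentrations: pd.DataFrame,
    receptors: list[Receptor],
    links: list[Link],
    met_series: list[MetHour],
    ht_aadt_min: float = 50000.0,
    cos_cap: float = 0.1,
) -> pd.DataFrame:
    """Mean concentration vs mean effective distance, per receptor.

    The effective distance to the receptor's nearest high-traffic link is
    averaged over valid hours in which the receptor is downwind; hours
    with the receptor effectively upwind are excluded from the distance
    average (a receptor never downwind gets no distance, but its mean
    concentration is still reported).

    Returns (receptor_id, mean_c, mean_effective_m, n_downwind_hours).
    """
    ht_links = [l for l in links if l.aadt >= ht_aadt_min]
    valid_hours = [m for m in met_series if hour_valid(m)]
    conc = concentrations[concentrations["valid"]]
    mean_c = conc.groupby("receptor_id", observed=True)["c"].mean()
    rows = []
    for rec in receptors:
        nearest = min(
            ht_links,
            key=lambda l: perpendicular_distance(l, (rec.x, rec.y)),
            default=None,
        )
        d_effs = []
        if nearest is not None:
            for m in valid_hours:
                d = effective_distance(nearest, rec, m.wdir % 360.0, cos_cap=cos_cap)
                if d is not None:
                    d_effs.append(d)
        rows.append(
            {
                "receptor_id": rec.id,
                "mean_c": mean_c.get(rec.id, np.nan),
                "mean_effective_m": float(np.mean(d_effs)) if d_effs else np.nan,
                "n_downwind_hours": len(d_effs),
            }
        )
    return pd.DataFrame(rows)


def exposure_constants_kwargs(c: ExposureConstants) -> dict:
    """classify_receptors keyword arguments from an ExposureConstants."""
    return {
        "ht_aadt_min": c.ht_aadt_min,
        "near_m": c.near_m,
        "verynear_m": c.verynear_m,
    }
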