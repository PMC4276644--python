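"""Steady-state Gaussian line-source dispersion at unit emission rate.

Each road link is integrated as a line of Gaussian point-plume elements
driven by hourly Monin-Obukhov surface meteorology, yielding chi: the
concentration at a receptor (ug/m^3) per unit line-source emission rate
(1 g/m/s). Emissions enter later as pure scaling factors (the decoupling
that lets activity or fleet-mix adjustments be applied without re-running
dispersion).

The plume component uses a crosswind-Gaussian kernel with ground and
mixing-lid image reflections; a low-wind meander component spreads a
fraction f_m = min(1, 2*sigma_v^2/u_e^2) of the material radially over
all directions, which is what produces the observed nonzero upwind
concentrations close to a road in calm, stable hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DispersionConstants
from .network import Link, Receptor, transport_unit_vector

__all__ = [
    "MetHour",
    "DerivedMet",
    "ChiMatrix",
    "classify_stability",
    "derive_met",
    "sigma_curves",
    "unit_concentration",
    "build_chi_matrix",
    "normalized_profile",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class MetHour:
    """One hour of surface meteorology.

    ustar: friction velocity (m/s); L: Monin-Obukhov length (m);
    zic/zim: convective/mechanical mixing heights (m), zic may be None
    in stable hours; z0: roughness length (m); u: wind speed (m/s);
    wdir: direction the wind blows from (degrees clockwise from north);
    temp_f: temperature (Fahrenheit). `complete` is False when any
    required field was missing in the source record.
    """

    timestamp: pd.Timestamp
    ustar: float | None = None
    L: float | None = None
    zic: float | None = None
    zim: float | None = None
    z0: float | None = None
    u: float | None = None
    wdir: float | None = None
    temp_f: float | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.complete:
            required = ("ustar", "L", "zim", "z0", "u", "wdir", "temp_f")
            for name in required:
                v = getattr(self, name)
                if v is None or not math.isfinite(v):
                    raise ValueError(
                        f"met hour {self.timestamp}: {name} missing but complete=True"
                    )
            if self.L < 0 and (self.zic is None or not math.isfinite(self.zic)):
                raise ValueError(
                    f"met hour {self.timestamp}: zic required when L < 0"
                )
            if not (self.ustar > 0 and self.zim > 0 and self.z0 > 0 and self.u >= 0):
                raise ValueError(f"met hour {self.timestamp}: invalid surface parameters")


@dataclass(frozen=True)
class DerivedMet:
    """Turbulence scales derived from one complete met hour."""

    wstar: float
    sigma_v: float
    sigma_w: float
    u_e: float
    z_mix: float
    stability_class: str
    L: float
    wdir: float


def classify_stability(L: float) -> str:
    """Stability regime from the Monin-Obukhov length.

    |L| > 500 m -> neutral; 100 < L <= 500 -> stable;
    0 < L <= 100 -> very_stable; -500 <= L < 0 -> convective.
    """
    if L is None or not math.isfinite(L) or L == 0.0:
        raise ValueError("L must be finite and nonzero")
    if abs(L) > 500.0:
        return "neutral"
    if L > 100.0:
        return "stable"
    if L > 0.0:
        return "very_stable"
    return "convective"


def derive_met(m: MetHour, c: DispersionConstants = DispersionConstants()) -> DerivedMet:
    """Turbulence scales from a complete met hour.

    wstar = ustar*(zic/(kappa*|L|))^(1/3) for convective hours, else 0;
    sigma_v/sigma_w combine shear- and buoyancy-driven parts in quadrature
    with floors; the effective transport speed u_e = sqrt(u^2 + 2 sigma_v^2)
    keeps near-calm hours finite; the lid z_mix is max(zic, zim) when
    convective, else the mechanical mixing height.
    """
    if not m.complete:
        raise ValueError(f"met hour {m.timestamp} is incomplete")
    if m.L == 0.0:
        raise ValueError("L = 0 is undefined")
    stability = classify_stability(m.L)
    if m.L < 0:
        z_mix = max(m.zic, m.zim)
        # buoyant velocity scale only where buoyancy dominates; near-neutral
        # hours (|L| large) are shear-driven even when L is slightly negative
        wstar = (
            m.ustar * (m.zic / (c.kappa * abs(m.L))) ** (1.0 / 3.0)
            if stability == "convective"
            else 0.0
        )
    else:
        wstar = 0.0
        z_mix = m.zim
    sigma_v = max(math.hypot(c.a_v * m.ustar, c.b_conv * wstar), c.sigma_v_min)
    sigma_w = max(math.hypot(c.a_w * m.ustar, c.b_conv * wstar), c.sigma_w_min)
    u_e = math.sqrt(m.u**2 + 2.0 * sigma_v**2)
    return DerivedMet(
        wstar=wstar,
        sigma_v=sigma_v,
        sigma_w=sigma_w,
        u_e=u_e,
        z_mix=z_mix,
        stability_class=stability,
        L=m.L,
        wdir=m.wdir,
    )


def _vertical_time_scale(d: DerivedMet, c: DispersionConstants) -> float:
    """T_z such that sigma_z = sigma_w*t*(1+t/T_z)^(-1/2); inf => ballistic."""
    if d.stability_class in ("stable", "very_stable"):
        return c.t_z_stable_coeff * abs(d.L) / d.sigma_w
    if d.stability_class == "neutral":
        return c.t_z_neutral_coeff * d.z_mix / d.sigma_w
    return math.inf


def sigma_curves(
    x, d: DerivedMet, c: DispersionConstants = DispersionConstants()
) -> tuple[np.ndarray, np.ndarray]:
    """Lateral and vertical plume spreads (m) at downwind distance x (m).

    Both are strictly increasing in x; near the source they grow
    ballistically as sigma_v*t and sigma_w*t with t = x/u_e.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance must be > 0")
    t = x / d.u_e
    sigma_y = d.sigma_v * t / np.sqrt(1.0 + t / c.t_y)
    t_z = _vertical_time_scale(d, c)
    sigma_z = d.sigma_w * t / np.sqrt(1.0 + t / t_z)
    return sigma_y, sigma_z


# ---------------------------------------------------------------------------
# Vectorized kernel
# ---------------------------------------------------------------------------


class _HourArrays:
    """Per-hour derived-met vectors for the batched kernel."""

    def __init__(self, derived: list[DerivedMet], c: DispersionConstants):
        self.u_e = np.array([d.u_e for d in derived])
        self.sigma_v = np.array([d.sigma_v for d in derived])
        self.sigma_w = np.array([d.sigma_w for d in derived])
        self.z_mix = np.array([d.z_mix for d in derived])
        self.t_z = np.array([_vertical_time_scale(d, c) for d in derived])
        uv = np.array([transport_unit_vector(d.wdir) for d in derived])
        self.utx = uv[:, 0]
        self.uty = uv[:, 1]
        self.f_m = np.minimum(1.0, 2.0 * self.sigma_v**2 / self.u_e**2)
        self.n = len(derived)


def _vertical_term(
    sig_z: np.ndarray,
    z_mix: np.ndarray,
    z_r: float,
    h: float,
    c: DispersionConstants,
) -> np.ndarray:
    """Ground- and lid-image vertical distribution, 1/z_mix once well mixed."""
    s2 = 2.0 * sig_z**2
    tot = np.exp(-((z_r - h) ** 2) / s2) + np.exp(-((z_r + h) ** 2) / s2)
    # image pairs only matter once the plume depth approaches the lid
    if np.any(sig_z > 0.3 * z_mix):
        for k in range(1, c.n_images + 1):
            off = 2.0 * k * z_mix
            for o in (off, -off):
                tot = tot + np.exp(-((z_r - h + o) ** 2) / s2)
                tot = tot + np.exp(-((z_r + h + o) ** 2) / s2)
    v = tot / (_SQRT_2PI * sig_z)
    return np.where(sig_z > c.lid_factor * z_mix, 1.0 / z_mix, v)


def _element_midpoints(verts: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """n equal-arclength element midpoints along a polyline; returns (mx, my, dl)."""
    seg = np.hypot(*np.diff(verts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = (np.arange(n) + 0.5) * (total / n)
    mx = np.interp(s, cum, verts[:, 0])
    my = np.interp(s, cum, verts[:, 1])
    return mx, my, total / n


def _chi_eval(
    verts: np.ndarray,
    rx: float,
    ry: float,
    z_r: float,
    met: _HourArrays,
    c: DispersionConstants,
    n: int,
) -> np.ndarray:
    """chi (ug/m^3 per g/m/s) for one link-receptor pair over all hours, n elements."""
    mx, my, dl = _element_midpoints(verts, n)
    dx = (rx - mx)[:, None]  # (n, 1)
    dy = (ry - my)[:, None]
    x = dx * met.utx + dy * met.uty          # downwind distance (n, T)
    ycr = -dx * met.uty + dy * met.utx       # signed crosswind offset (n, T)

    downwind = x > c.x_min
    xs = np.where(downwind, x, 1.0)          # safe placeholder off-mask
    t = xs / met.u_e
    sig_y = met.sigma_v * t / np.sqrt(1.0 + t / c.t_y)
    sig_z = met.sigma_w * t / np.sqrt(1.0 + t / met.t_z)
    plume = (
        dl
        / (_SQRT_2PI * sig_y * met.u_e)
        * np.exp(-(ycr**2) / (2.0 * sig_y**2))
        * _vertical_term(sig_z, met.z_mix, z_r, c.source_height, c)
    )
    chi_p = np.where(downwind, plume, 0.0).sum(axis=0)

    if c.meander:
        r = np.maximum(np.hypot(dx, dy), c.x_min)  # (n, 1)
        t_r = r / met.u_e
        sig_zr = met.sigma_w * t_r / np.sqrt(1.0 + t_r / met.t_z)
        mnd = (
            dl
            / (2.0 * math.pi * r * met.u_e)
            * _vertical_term(sig_zr, met.z_mix, z_r, c.source_height, c)
        )
        chi = (1.0 - met.f_m) * chi_p + met.f_m * mnd.sum(axis=0)
    else:
        chi = chi_p
    return chi * 1.0e6  # g/m^3 -> ug/m^3


_HOUR_CHUNK = 256


def _min_distance(verts: np.ndarray, rx: float, ry: float) -> float:
    """Distance from a point to a polyline (segment-clamped)."""
    a = verts[:-1]
    b = verts[1:]
    ab = b - a
    ap = np.array([rx, ry]) - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / np.where(denom > 0, denom, 1.0), 0, 1)
    nearest = a + t[:, None] * ab
    return float(np.min(np.hypot(rx - nearest[:, 0], ry - nearest[:, 1])))


def _start_elements(verts: np.ndarray, rx: float, ry: float, c: DispersionConstants) -> int:
    """Starting element count resolving the plume width at the receptor.

    Node doubling from an arbitrarily coarse start can falsely converge
    (successive near-zero sums) when no element falls within a few
    sigma_y of the receptor's crosswind window, so the start spacing is
    tied to the receptor's distance from the line.
    """
    total = float(np.hypot(*np.diff(verts, axis=0).T).sum())
    spacing = max(0.3 * _min_distance(verts, rx, ry), 1.0)
    n = 1 << max(int(np.ceil(np.log2(max(total / spacing, 1.0)))), 0)
    return int(min(max(n, c.n_start), c.n_max // 2))


def _chi_pair(
    verts: np.ndarray,
    rx: float,
    ry: float,
    z_r: float,
    met: _HourArrays,
    c: DispersionConstants,
) -> np.ndarray:
    """Adaptive node-doubling line integration for one link-receptor pair."""
    out = np.empty(met.n)
    n0 = _start_elements(verts, rx, ry, c)
    for lo in range(0, met.n, _HOUR_CHUNK):
        hi = min(lo + _HOUR_CHUNK, met.n)
        sub = _HourArrays.__new__(_HourArrays)
        for name in ("u_e", "sigma_v", "sigma_w", "z_mix", "t_z", "utx", "uty", "f_m"):
            setattr(sub, name, getattr(met, name)[lo:hi])
        sub.n = hi - lo
        n = n0
        prev = _chi_eval(verts, rx, ry, z_r, sub, c, n)
        while n < c.n_max:
            n *= 2
            cur = _chi_eval(verts, rx, ry, z_r, sub, c, n)
            gmax = max(float(np.max(cur)), 1e-300)
            denom = np.maximum(np.maximum(np.abs(cur), np.abs(prev)), 1e-9 * gmax)
            if float(np.max(np.abs(cur - prev) / denom)) <= c.rel_tol:
                prev = cur
                break
            prev = cur
        out[lo:hi] = prev
    return out


def unit_concentration(
    link: Link,
    receptor: Receptor,
    m: MetHour,
    c: DispersionConstants = DispersionConstants(),
) -> float:
    """chi at one receptor for one hour: ug/m^3 per unit emission (1 g/m/s)."""
    if not m.complete:
        raise ValueError(f"met hour {m.timestamp} is incomplete")
    if link.line.distance(receptor.point) < c.x_min:
        raise ValueError(
            f"receptor {receptor.id!r} lies within x_min of link {link.id!r}; "
            "on-road concentrations are undefined"
        )
    met = _HourArrays([derive_met(m, c)], c)
    return float(_chi_pair(link.geometry, receptor.x, receptor.y, receptor.height, met, c)[0])


@dataclass
class ChiMatrix:
    """Unit-emission concentrations indexed (link, receptor, hour).

    values holds NaN for hours failing validity (calm or incomplete
    meteorology); those hours are masked, never zero-filled. chi is
    independent of emissions, so the matrix is computed once and reused
    across any emissions scenario.
    """

    link_ids: list[str]
    receptor_ids: list[str]
    timestamps: pd.DatetimeIndex
    values: np.ndarray  # (n_links, n_receptors, n_hours)
    valid: np.ndarray  # (n_hours,) bool

    def to_long_frame(self) -> pd.DataFrame:
        """Loss-free long form (link_id, receptor_id, timestamp, chi)."""
        li, ri, ti = np.meshgrid(
            np.arange(len(self.link_ids)),
            np.arange(len(self.receptor_ids)),
            np.arange(len(self.timestamps)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "link_id": np.asarray(self.link_ids, dtype=object)[li.ravel()],
                "receptor_id": np.asarray(self.receptor_ids, dtype=object)[ri.ravel()],
                "timestamp": self.timestamps[ti.ravel()],
                "chi": self.values.ravel(),
            }
        )


def build_chi_matrix(
    links: list[Link],
    receptors: list[Receptor],
    met_series: list[MetHour],
    c: DispersionConstants = DispersionConstants(),
) -> ChiMatrix:
    """chi for every (link, receptor, valid hour); invalid hours masked."""
    from .exposure import hour_valid  # deferred: exposure owns the validity rule

    if not links or not receptors:
        raise ValueError("links and receptors must both be nonempty")
    timestamps = pd.DatetimeIndex([m.timestamp for m in met_series])
    valid = np.array([hour_valid(m) for m in met_series], dtype=bool)
    derived = [derive_met(m, c) for m, ok in zip(met_series, valid) if ok]
    values = np.full((len(links), len(receptors), len(met_series)), np.nan)
    if derived:
        met = _HourArrays(derived, c)
        idx = np.flatnonzero(valid)
        for i, link in enumerate(links):
            for j, rec in enumerate(receptors):
                if link.line.distance(rec.point) < c.x_min:
                    raise ValueError(
                        f"receptor {rec.id!r} lies within x_min of link {link.id!r}"
                    )
                values[i, j, idx] = _chi_pair(
                    link.geometry, rec.x, rec.y, rec.height, met, c
                )
    return ChiMatrix(
        link_ids=[l.id for l in links],
        receptor_ids=[r.id for r in receptors],
        timestamps=timestamps,
        values=values,
        valid=valid,
    )


def normalized_profile(chi_along_transect) -> np.ndarray:
    """Transect concentrations divided by the value closest to the road."""
    chi = np.asarray(chi_along_transect, dtype=float)
    if chi.size == 0 or not chi[0] > 0:
        raise ValueError("first (closest-to-road) value must be > 0")
    return chi / chi[0]
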