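"""Named constants for every tunable in the pipeline, with YAML loading.

Each stage takes its constants object explicitly so a single config file
can drive a reproducible run; defaults here are the package's normative
values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class DispersionConstants:
    """Constants of the Gaussian line-source kernel.

    All lengths in meters, times in seconds, speeds in m/s.
    """

    #: von Karman constant (convective velocity scale).
    kappa: float = 0.4
    #: sigma_v = max(sqrt((a_v*ustar)^2 + (b_conv*wstar)^2), sigma_v_min)
    a_v: float = 1.9
    #: sigma_w = max(sqrt((a_w*ustar)^2 + (b_conv*wstar)^2), sigma_w_min)
    a_w: float = 2.0
    b_conv: float = 0.6
    sigma_v_min: float = 0.2
    sigma_w_min: float = 0.1
    #: lateral spread time scale T_y (s): sigma_y = sigma_v*t*(1+t/T_y)^-1/2
    t_y: float = 600.0
    #: stable vertical time scale T_z = t_z_stable_coeff*|L|/sigma_w
    t_z_stable_coeff: float = 2.0
    #: neutral vertical time scale T_z = t_z_neutral_coeff*z_mix/sigma_w
    t_z_neutral_coeff: float = 1.0
    #: once sigma_z > lid_factor*z_mix the vertical term becomes well mixed (1/z_mix)
    lid_factor: float = 1.2
    #: number of ground/lid image pairs on each side in the vertical term
    n_images: int = 2
    #: elements closer than x_min downwind contribute meander only
    x_min: float = 1.0
    #: effective release height of the roadway plume (vehicle wake) in m
    source_height: float = 1.0
    #: default receptor (breathing) height in m
    receptor_height: float = 1.5
    #: adaptive line-integration relative tolerance
    rel_tol: float = 1e-3
    #: low-wind meander component on/off
    meander: bool = True
    #: starting and maximum element counts for adaptive node doubling
    n_start: int = 16
    n_max: int = 16384


@dataclass(frozen=True)
class ExposureConstants:
    """Validity, completeness, and cohort-classification constants."""

    #: hours with wind speed below this (m/s) are invalid for dispersion
    min_wind_speed: float = 0.5
    #: fraction of valid hours a day*period cell needs to be reported
    completeness: float = 0.75
    #: AADT at or above which a link counts as high traffic (veh/day)
    ht_aadt_min: float = 50000.0
    #: cohort classification radius (m)
    near_m: float = 300.0
    #: reported sub-flag radius (m)
    verynear_m: float = 150.0
    #: receptors are upwind when cos(angle to road normal) <= cos_cap;
    #: also caps effective distance at d_perp/cos_cap
    cos_cap: float = 0.1


@dataclass(frozen=True)
class AdjustmentConstants:
    """Local-measurement adjustment constants."""

    #: multiplicative AADT factor applied to interstates (NFC 11)
    interstate_factor: float = 0.8
    #: calendar year whose traffic-recorder records drive adjustments
    study_year: int = 2010


@dataclass(frozen=True)
class Constants:
    dispersion: DispersionConstants = field(default_factory=DispersionConstants)
    exposure: ExposureConstants = field(default_factory=ExposureConstants)
    adjustment: AdjustmentConstants = field(default_factory=AdjustmentConstants)


def load_constants(path: str | Path | None) -> Constants:
    """Load constants from a YAML file of section -> {name: value} overrides.

    Unknown keys raise, so typos in a config never pass silently.
    """
    if path is None:
        return Constants()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {}
    defaults = Constants()
    for section in ("dispersion", "exposure", "adjustment"):
        base = getattr(defaults, section)
        overrides = raw.pop(section, {}) or {}
        known = {f.name for f in dataclasses.fields(base)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown {section} constants: {sorted(unknown)}")
        sections[section] = dataclasses.replace(base, **overrides)
    if raw:
        raise ValueError(f"unknown config sections: {sorted(raw)}")
    return Constants(**sections)
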