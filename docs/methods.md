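# Methods

This note documents the models implemented in `nearroad`, the choices
made where the design was genuinely open, and what the packaged
synthetic scenario does and does not establish about real data.

## Emissions

Hourly link emissions follow the standard bottom-up decomposition
`E_i = EF_i × A_i`. The composite emission factor `EF_i` is the
fleet-mix-weighted sum of class-specific emission factors; the eight
vehicle classes are the MOBILE-style fuel/duty split (LDGV, LDGT1,
LDGT2, HDGV, MC, LDDV, LDDT, HDDV). Lookups snap to the nearest
temperature bin (0–100 °F by 10) and speed bin (2.5 mph, then 5–75 by
5), with exact midpoints rounding up and out-of-range values clamping
to the edge bins. One roadway speed applies to all vehicle classes on
a link, per modeled time period of day (off-peak 0–6, AM peak 7–8,
midday 9–15, PM peak 16–18, off-peak 19–23; the two off-peak periods
share a speed and the loader fills one from the other).

Two normalization conventions are deliberate:

- **Fleet mixes** are renormalized to sum exactly 1 inside
  `composite_ef` (printed catalog columns sum to ~100% with rounding),
  but `diesel_fraction` sums the *raw* printed fractions so the
  packaged columns reproduce their stated diesel percentages (9.18%
  interstate, 5.23% freeway/arterial) exactly.
- **Temporal allocation factors** are defined so that hourly factors
  sum to 1 within each daytype (weekday/weekend) and day-of-week and
  month factors each average to 1. This makes AADT the annual-average
  daily total: over a full year, hourly activity sums to 365 × AADT to
  within ~0.1% (the residual comes from the weekday/weekend imbalance
  of a 365-day calendar). Holidays are treated as their weekday.

The line-source strength used by dispersion is
`q = E_i / 1609.344 / 3600` (g/m/s from g/mile/hour).

## Dispersion

Dispersion is a steady-state Gaussian line-source kernel evaluated at
unit emission rate (1 g/m/s). Each link is discretized into elements;
for an element at downwind distance `x > x_min` and crosswind offset
`y` from the receptor, the plume contribution is

```
dl / (sqrt(2π) σ_y u_e) · exp(−y²/2σ_y²) · V(z_r)
```

with the vertical term `V` summing a ground and elevated-source image
pair plus two mixing-lid image pairs on each side, replaced by the
well-mixed value `1/z_mix` once `σ_z > 1.2 z_mix`. A meander component
redistributes the fraction `f_m = min(1, 2σ_v²/u_e²)` of the material
radially over all directions (elements contribute `dl/(2π r u_e)·V`
regardless of wind direction), which is what produces nonzero upwind
concentrations near a road in light-wind stable hours. Meander is on
by default and exposed as a flag.

Surface-layer scales derive from the hourly meteorology:

- stability regimes from the Monin-Obukhov length: neutral for
  |L| > 500 m, stable for 100 < L ≤ 500, very stable for 0 < L ≤ 100
  (values in (0, 1] are folded into very stable), convective for
  −500 ≤ L < 0. Band edges follow the inclusive inequalities above.
- `w* = u*(z_ic/(κ|L|))^{1/3}` for hours classified convective, zero
  otherwise. Treating near-neutral negative-L hours (|L| > 500) as
  shear-driven keeps the neutral regime's turbulence consistent with
  its u* (σ_v = 1.9 u* for the representative neutral hour).
- `σ_v = max(√((a_v u*)² + (0.6 w*)²), 0.2)` and likewise σ_w with
  coefficient `a_w` and floor 0.1 m/s; the effective transport speed
  `u_e = √(u² + 2σ_v²)` keeps near-calm hours finite.
- lateral spread `σ_y = σ_v t (1+t/T_y)^{-1/2}` with `T_y = 600 s` and
  `t = x/u_e`; vertical spread `σ_z = σ_w t (1+t/T_z)^{-1/2}` with
  `T_z = 2|L|/σ_w` (stable/very stable), `T_z = t_zn·z_mix/σ_w`
  (neutral), and ballistic growth (T_z = ∞) for convective hours.
- the lid `z_mix` is max(z_ic, z_im) when L < 0, else z_im.

**Calibration.** The σ-coefficients were calibrated once, within a
factor of two of their initial values, against the regime-level shape
constraint that convective and neutral hours produce near-identical
normalized concentration-versus-distance profiles while the stability
ordering χ(very stable) > χ(stable) > χ(neutral) at 100 m, flux
conservation, and the full property suite all hold. The shipped values
are `a_v = 1.9`, `a_w = 2.0`, `t_zn = 1.0`. The dominant sensitivity is
σ_z at the profile-normalization distance (~10 m): with a smaller
`a_w`, the shear-driven neutral σ_z near the source is too small
relative to the buoyancy-driven convective σ_z, and the vertical
source/receptor-height factor then separates the two normalized
profiles by >10%.

**Numerics.** The line integral uses equal-arclength midpoint elements
with successive node doubling to a relative tolerance of 1e-3. The
starting element count resolves the receptor's distance to the line
(spacing ≈ 0.3 × distance), because doubling from an arbitrarily
coarse start can falsely converge when no element lands within a few
σ_y of the receptor's crosswind window. Hours are processed in blocks
of 256 with all per-hour quantities vectorized; the element count is
capped at 16384. Receptors closer than `x_min = 1 m` to a link
centerline are rejected (on-road concentrations are undefined in this
kernel). Source height is 1.0 m (vehicle-wake release), receptor
default 1.5 m (breathing height). Against a 10,000-element uniform
oracle the adaptive integral agrees to <0.5% across random
link/receptor/met configurations; the ground-level infinite-line
closed form `√(2/π)/(u_e σ_z)` is matched to <1% in its validity
regime, and the downwind plane flux recovers the emitted rate to <2%
with meander off.

## Exposure

An hour is valid iff the meteorological record is complete and wind
speed ≥ 0.5 m/s (inclusive at the boundary). A day × period cell is
reported iff valid_hours/period_hours ≥ 0.75 (inclusive); daily
averages apply the same rule over 24 hours. Cohorts: HTHD if within
300 m of any high-traffic (AADT ≥ 50,000) high-diesel link, with HD
taking precedence when a receptor is in range of both HD and LD links;
else HTLD within 300 m of a high-traffic low-diesel link; else LT.
A 150 m sub-flag and the nearest high-traffic link are recorded. HD/LD
designation defaults to NFC 11 = HD, NFC 12 = LD and follows the
assigned fleet mix after measurement-driven reassignment.

Cohort–period statistics pool valid hourly concentrations per cohort
(the per-receptor-then-pool alternative gives the same orderings on
the packaged scenario but weights receptors rather than hours).

Effective distance to the nearest high-traffic link is
`d_perp / cos θ`, θ the angle between the hourly transport direction
(wind-from + 180°) and the road normal toward the receptor; hours with
`cos θ ≤ 0.1` count as upwind and are excluded from per-receptor
average effective distance (the cap also bounds d_eff at 10 d_perp).

## Adjustments

Traffic recorders provide measured AADT and commercial AADT (CAADT).
Three procedures:

- `compare_aadt`: 100 × (model − measured)/measured per link-year.
- `rescale_aadt`: interstates (NFC 11) scaled by 0.8 by default; the
  removed vehicle-meters-traveled are added back uniformly per meter of
  freeway (NFC 12), conserving network VMT to machine precision. The
  uniform per-meter increment is the exact-conservation reading of
  "redistribute by the length ratio"; a per-link override hook exists.
- `reassign_diesel`: CAADT/AADT is equated to the diesel share (an
  approximation — commercial vehicles are predominantly but not
  exclusively diesel); each measured link is switched to the catalog
  mix whose diesel percentage is nearest the measurement, ties keeping
  the original. Nearest-mix assignment (rather than a fixed threshold)
  works for catalogs with more than two mixes. AADT is never touched
  here, and the rescale never touches mixes.

Receptors whose label moves HTHD → HTLD keep a dedicated `HD_to_LD`
label for reporting. Because dispersion ran at unit emissions, both
adjustments rescore against the stored χ matrix unchanged.

## Synthetic scenario

The default scenario (seeded, fully deterministic) is sized to run the
whole pipeline in minutes on one CPU: two parallel 9 km corridors of
six 1500 m links (NFC 11 interstate and NFC 12 freeway, 95,000 AADT
± 5% per link, speeds 48–55 and 46–52 mph by period), four
cross-streets (NFC 14/16/17/19 with AADTs 16,000 down to 1,500),
10 + 10 receptors in east/west pairs at shared 25–280 m perpendicular
distances along each corridor, and 10 far low-traffic receptors. The
corridors are offset along the crosswind (NE–SW) axis of the
prevailing northwest transport and given identical lengths and
receptor margins, so neither cohort systematically inherits the other
corridor's plume: the cohorts are constructed to differ in fleet
composition, not geometry. A full city-scale setup (thousands of
links, ~160 receptors) is a matter of raising the corridor/receptor
counts in `ScenarioSpec`; the tests use the toy scale only.

Meteorology cycles a diurnal stability schedule (stable nights, very
stable 03:00–08:59 lasting through the morning rush, convective
middays, neutral evenings) with parameters jittered log-normally
(15%) around the four packaged representative regime rows and clamped
to their L-bands; wind directions are von Mises around 315° (κ = 2);
5% of hours are calm (u < 0.5 m/s) and 2% incomplete. At zero jitter
the regime rows are reproduced verbatim.

The EF generator builds complete axes for three pollutants: a
diesel-marker (diesel classes 0.30, gasoline 0.01 g/veh/mi; HD/LD
fleet ratio 1.45), an intermediate (0.20/0.02; ratio 1.24), and a
class-uniform traffic marker (5.0 everywhere; ratio exactly 1), all
sharing a mild U-shaped speed dependence (minimum near 45 mph), a weak
cold-temperature increase, and a summer-high month cycle. The absolute
magnitudes are arbitrary; only the class-contrast structure is
meaningful. TAFs have weekday bimodal rush peaks (7–8 AM and 5–6 PM),
a single weekend mode at 4 PM, lower weekend day-of-week factors, and
a summer-high month cycle.

Traffic-recorder records cover both corridors for 2009–2011 with a
+20% model-overestimate bias (σ = 3%) on interstates; measured diesel
shares alternate ≈9% / ≈5% along the interstate and are ≈5% on the
freeway, so the reassignment switches part of the interstate to the
low-diesel mix and reclassifies the receptors near it.

**What passing tests show — and don't.** The scenario exercises every
pipeline branch (calm and incomplete hours, both cohorts, upwind
receptors, reclassifiable links) and its constructed contrasts let the
end-to-end checks assert the qualitative patterns the method is
designed to resolve: diesel-marker separation between cohorts, traffic
-marker symmetry, the AM-peak exposure maximum under the stable-rush
schedule, and the shrinking cohort gap after measurement-driven
adjustments. It does not emulate real street-network irregularity,
terrain or noise barriers, chemistry (no NO2), spatially varying
meteorology, or hour-specific traffic events (jams, detours), so
passing here demonstrates internal correctness and sensitivity
structure, not predictive accuracy for any real domain.

## Known limitations

- Flat, at-grade roadways only; no barriers, depressions, deposition,
  plume rise, or chemistry.
- One meteorological series for the whole domain.
- The dispersion parameterization is a compact research kernel, not a
  regulatory model; its constants live in one config
  (`DispersionConstants`) and the property suite is the contract any
  re-tuning must satisfy.
- Polyline links are treated exactly; there is no geodesy, so all
  inputs must share one projected CRS in meters.
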