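"""The Gaussian line-source kernel: stability, turbulence scales, sigma
curves, the numerical line integral against independent oracles, and the
regime-level behavior of chi."""

import math

import numpy as np
import pandas as pd
import pytest

from nearroad.config import DispersionConstants
from nearroad.dispersion import (
    MetHour,
    _HourArrays,
    _chi_pair,
    build_chi_matrix,
    classify_stability,
    derive_met,
    normalized_profile,
    sigma_curves,
    unit_concentration,
)
from nearroad.network import Link, Receptor
from nearroad.reference import STABILITY_REGIMES
from tests.conftest import regime_met_hour

SQRT_2PI = math.sqrt(2.0 * math.pi)


def chi_at(link, x, y, regime, c, z_r=1.5, wdir=270.0):
    m = regime_met_hour(regime, wdir=wdir)
    met = _HourArrays([derive_met(m, c)], c)
    return float(_chi_pair(link.geometry, x, y, z_r, met, c)[0])


class TestStability:
    @pytest.mark.parametrize(
        "L,expected",
        [
            (-12.9, "convective"),
            (104.5, "stable"),
            (12.8, "very_stable"),
            (-1223.7, "neutral"),
            (0.5, "very_stable"),  # (0,1] treated as very stable
            (100.0, "very_stable"),  # inclusive band edge
            (500.0, "stable"),
            (-500.0, "convective"),
            (501.0, "neutral"),
        ],
    )
    def test_bands(self, L, expected):
        assert classify_stability(L) == expected

    def test_zero_and_nonfinite_rejected(self):
        for bad in (0.0, float("nan"), float("inf")):
            with pytest.raises(ValueError):
                classify_stability(bad)


class TestDeriveMet:
    def test_convective_wstar(self, constants):
        """wstar = 0.229*(80/(0.4*12.9))^(1/3) = 0.571 m/s by hand."""
        d = derive_met(regime_met_hour("convective"), constants)
        assert d.wstar == pytest.approx(0.229 * (80.0 / (0.4 * 12.9)) ** (1 / 3),
                                        rel=1e-12)
        assert d.wstar == pytest.approx(0.571, abs=5e-4)
        assert d.z_mix == 252.0  # max(zic, zim)

    def test_neutral_shear_driven(self, constants):
        """Near-neutral hours are shear-driven: sigma_v = 1.9*ustar."""
        d = derive_met(regime_met_hour("neutral"), constants)
        assert d.wstar == 0.0
        assert d.sigma_v == pytest.approx(1.9 * 0.734, rel=1e-12)  # 1.3946
        assert d.u_e == pytest.approx(math.sqrt(4.63**2 + 2 * 1.3946**2), rel=1e-6)
        assert d.u_e == pytest.approx(5.033, abs=1e-3)

    def test_stable_wstar_zero(self, constants):
        d = derive_met(regime_met_hour("stable"), constants)
        assert d.wstar == 0.0
        assert d.z_mix == 294.0  # mechanical mixing height when L > 0

    def test_u_e_at_least_u_and_floors(self, constants):
        for regime in STABILITY_REGIMES:
            m = regime_met_hour(regime)
            d = derive_met(m, constants)
            assert d.u_e >= m.u
            assert d.sigma_v >= constants.sigma_v_min
            assert d.sigma_w >= constants.sigma_w_min

    def test_incomplete_hour_rejected(self, constants):
        m = regime_met_hour("neutral")
        m.complete = False
        with pytest.raises(ValueError, match="incomplete"):
            derive_met(m, constants)


class TestSigmaCurves:
    @pytest.mark.parametrize("regime", list(STABILITY_REGIMES))
    def test_ballistic_near_source_limit(self, regime, constants):
        d = derive_met(regime_met_hour(regime), constants)
        x = 0.05
        sy, sz = sigma_curves(x, d, constants)
        t = x / d.u_e
        assert sy == pytest.approx(d.sigma_v * t, rel=1e-3)
        assert sz == pytest.approx(d.sigma_w * t, rel=1e-3)

    @pytest.mark.parametrize("regime", list(STABILITY_REGIMES))
    def test_strictly_increasing(self, regime, constants):
        d = derive_met(regime_met_hour(regime), constants)
        x = np.linspace(1.0, 2000.0, 400)
        sy, sz = sigma_curves(x, d, constants)
        assert np.all(np.diff(sy) > 0)
        assert np.all(np.diff(sz) > 0)

    def test_convective_sigma_z_exact(self, constants):
        """Convective growth is ballistic: sigma_z = sigma_w * x/u_e exactly."""
        d = derive_met(regime_met_hour("convective"), constants)
        _, sz = sigma_curves(100.0, d, constants)
        assert sz == pytest.approx(d.sigma_w * 100.0 / d.u_e, rel=1e-12)

    def test_nonpositive_x_rejected(self, constants):
        d = derive_met(regime_met_hour("neutral"), constants)
        with pytest.raises(ValueError):
            sigma_curves(0.0, d, constants)


def brute_force_chi(link, rx, ry, z_r, m, c, n=10000):
    """Independent uniform-element oracle for the line integral."""
    d = derive_met(m, c)
    verts = link.geometry
    seg = np.hypot(*np.diff(verts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = (np.arange(n) + 0.5) * (cum[-1] / n)
    mx = np.interp(s, cum, verts[:, 0])
    my = np.interp(s, cum, verts[:, 1])
    dl = cum[-1] / n
    b = math.radians((d.wdir + 180.0) % 360.0)
    ux, uy = math.sin(b), math.cos(b)
    if d.stability_class in ("stable", "very_stable"):
        t_z = c.t_z_stable_coeff * abs(d.L) / d.sigma_w
    elif d.stability_class == "neutral":
        t_z = c.t_z_neutral_coeff * d.z_mix / d.sigma_w
    else:
        t_z = math.inf

    def vterm(sz):
        s2 = 2.0 * sz**2
        tot = 0.0
        for k in range(-c.n_images, c.n_images + 1):
            off = 2.0 * k * d.z_mix
            tot += math.exp(-((z_r - c.source_height + off) ** 2) / s2)
            tot += math.exp(-((z_r + c.source_height + off) ** 2) / s2)
        if sz > c.lid_factor * d.z_mix:
            return 1.0 / d.z_mix
        return tot / (SQRT_2PI * sz)

    f_m = min(1.0, 2.0 * d.sigma_v**2 / d.u_e**2)
    chi_p = 0.0
    chi_m = 0.0
    for ex, ey in zip(mx, my):
        dx, dy = rx - ex, ry - ey
        xdown = dx * ux + dy * uy
        ycr = -dx * uy + dy * ux
        if xdown > c.x_min:
            t = xdown / d.u_e
            sy = d.sigma_v * t / math.sqrt(1.0 + t / c.t_y)
            sz = d.sigma_w * t / math.sqrt(1.0 + t / t_z)
            chi_p += (dl / (SQRT_2PI * sy * d.u_e)
                      * math.exp(-(ycr**2) / (2.0 * sy**2)) * vterm(sz))
        if c.meander:
            r = max(math.hypot(dx, dy), c.x_min)
            tr = r / d.u_e
            szr = d.sigma_w * tr / math.sqrt(1.0 + tr / t_z)
            chi_m += dl / (2.0 * math.pi * r * d.u_e) * vterm(szr)
    return ((1.0 - f_m) * chi_p + f_m * chi_m) * 1e6


class TestUnitConcentration:
    def test_mirror_symmetry_along_road_wind(self, straight_link, constants):
        """Receptors mirrored across the link under along-road wind see
        equal chi."""
        m = regime_met_hour("neutral", wdir=180.0)  # wind from south, along road
        a = unit_concentration(straight_link, Receptor(id="a", x=80.0, y=0.0), m,
                               constants)
        b = unit_concentration(straight_link, Receptor(id="b", x=-80.0, y=0.0), m,
                               constants)
        assert a == pytest.approx(b, rel=1e-6)
        assert a > 0

    def test_infinite_line_closed_form(self, constants):
        """Ground-level infinite-line limit: chi = sqrt(2/pi)/(u_e sigma_z)."""
        c = DispersionConstants(meander=False, source_height=0.0)
        link = Link(id="long", nfc=11, aadt=1.0,
                    speed_by_period={"offpeak1": 50.0, "ampeak": 50.0,
                                     "midday": 50.0, "pmpeak": 50.0},
                    geometry=np.array([[0.0, -5000.0], [0.0, 5000.0]]))
        m = regime_met_hour("neutral")
        d = derive_met(m, c)
        rec = Receptor(id="r", x=100.0, y=0.0, height=0.0)
        chi = unit_concentration(link, rec, m, c)
        _, sz = sigma_curves(100.0, d, c)
        closed = math.sqrt(2.0 / math.pi) / (d.u_e * sz) * 1e6
        assert chi == pytest.approx(closed, rel=0.01)

    def test_adaptive_vs_brute_force_random_configs(self, constants):
        """Adaptive node-doubling within 0.5% of a 10,000-element oracle
        over 20 random link/receptor/met configurations."""
        rng = np.random.default_rng(42)
        regimes = list(STABILITY_REGIMES)
        for i in range(20):
            x0, y0 = rng.uniform(-500, 500, 2)
            ang = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(300.0, 3000.0)
            verts = np.array([
                [x0, y0],
                [x0 + length * math.cos(ang), y0 + length * math.sin(ang)],
            ])
            link = Link(id=f"l{i}", nfc=11, aadt=1.0,
                        speed_by_period={"offpeak1": 50.0, "ampeak": 50.0,
                                         "midday": 50.0, "pmpeak": 50.0},
                        geometry=verts)
            # receptor offset from a random point of the link, kept well
            # off the line itself
            while True:
                tfrac = rng.uniform(0.1, 0.9)
                px = x0 + tfrac * (verts[1, 0] - x0)
                py = y0 + tfrac * (verts[1, 1] - y0)
                off = rng.uniform(20.0, 400.0)
                oang = rng.uniform(0, 2 * math.pi)
                rec = Receptor(id="r", x=px + off * math.cos(oang),
                               y=py + off * math.sin(oang))
                if link.line.distance(rec.point) >= 5.0:
                    break
            m = regime_met_hour(regimes[i % 4], wdir=rng.uniform(0, 360))
            got = unit_concentration(link, rec, m, constants)
            want = brute_force_chi(link, rec.x, rec.y, rec.height, m, constants)
            assert got == pytest.approx(want, rel=5e-3), f"config {i}"

    def test_flux_conservation(self, constants):
        """Total flux through a downwind plane recovers the emitted rate
        within 2% (meander off, sigma_z below the lid)."""
        from scipy.integrate import simpson

        c = DispersionConstants(meander=False)
        length = 200.0
        link = Link(id="seg", nfc=11, aadt=1.0,
                    speed_by_period={"offpeak1": 50.0, "ampeak": 50.0,
                                     "midday": 50.0, "pmpeak": 50.0},
                    geometry=np.array([[-length / 2, 0.0], [length / 2, 0.0]]))
        m = regime_met_hour("neutral", wdir=180.0)  # transport +y
        d = derive_met(m, c)
        x_plane = 100.0
        _, sz = sigma_curves(x_plane + length, d, c)
        assert sz < 0.8 * d.z_mix
        ys = np.linspace(-length / 2 - 500.0, length / 2 + 500.0, 161)
        zs = np.linspace(0.0, 8.0 * sz + c.source_height, 121)
        met = _HourArrays([d], c)
        conc = np.empty((len(zs), len(ys)))
        for zi, z in enumerate(zs):
            conc[zi] = [
                _chi_pair(link.geometry, y, x_plane, z, met, c)[0] for y in ys
            ]
        flux = simpson(simpson(conc, x=ys, axis=1), x=zs) * d.u_e  # ug/s
        emitted = length * 1e6  # 1 g/m/s over the link length, in ug/s
        assert flux == pytest.approx(emitted, rel=0.02)

    def test_upwind_nonzero_with_meander(self, straight_link, constants):
        """Low-wind stable hours spread material upwind of the road."""
        m = regime_met_hour("very_stable", wdir=90.0)  # receptor at +x is upwind
        rec = Receptor(id="r", x=20.0, y=0.0)
        chi_on = unit_concentration(straight_link, rec, m, constants)
        c_off = DispersionConstants(meander=False)
        chi_off = unit_concentration(straight_link, rec, m, c_off)
        assert chi_on > 0.0
        assert chi_off == pytest.approx(0.0, abs=1e-12)

    def test_stability_ordering_at_100m(self, straight_link, constants):
        """chi(very stable) > chi(stable) > chi(neutral) at 100 m downwind."""
        chis = {
            r: chi_at(straight_link, 100.0, 0.0, r, constants)
            for r in ("very_stable", "stable", "neutral")
        }
        assert chis["very_stable"] > chis["stable"] > chis["neutral"]

    def test_monotone_decay_downwind(self, straight_link, constants):
        for regime in STABILITY_REGIMES:
            xs = np.arange(5.0, 501.0, 5.0)
            chi = [chi_at(straight_link, x, 0.0, regime, constants) for x in xs]
            assert np.all(np.diff(chi) < 0), regime

    def test_linearity_superposition(self, straight_link, constants):
        """chi of two links equals the sum of single-link chis."""
        m = regime_met_hour("convective")
        other = Link(id="other", nfc=12, aadt=1.0,
                     speed_by_period={"offpeak1": 50.0, "ampeak": 50.0,
                                      "midday": 50.0, "pmpeak": 50.0},
                     geometry=np.array([[300.0, -2000.0], [300.0, 2000.0]]))
        rec = Receptor(id="r", x=150.0, y=0.0)
        a = unit_concentration(straight_link, rec, m, constants)
        b = unit_concentration(other, rec, m, constants)
        series = [m]
        chi = build_chi_matrix([straight_link, other], [rec], series, constants)
        assert chi.values[:, 0, 0].sum() == pytest.approx(a + b, rel=1e-9)

    def test_receptor_on_road_rejected(self, straight_link, constants):
        m = regime_met_hour("neutral")
        with pytest.raises(ValueError, match="x_min"):
            unit_concentration(straight_link, Receptor(id="r", x=0.5, y=0.0), m,
                               constants)


class TestChiMatrix:
    def met_series(self):
        out = []
        for h, regime in enumerate(("convective", "neutral", "stable", "very_stable")):
            m = regime_met_hour(regime)
            m.timestamp = pd.Timestamp("2010-08-02") + pd.Timedelta(hours=h)
            out.append(m)
        return out

    def test_four_regimes_unmasked(self, straight_link, constants):
        rec = Receptor(id="r", x=100.0, y=0.0)
        chi = build_chi_matrix([straight_link], [rec], self.met_series(), constants)
        assert chi.values.shape == (1, 1, 4)
        assert chi.valid.all()
        assert np.all(chi.values > 0)

    def test_calm_hour_masked_not_zeroed(self, straight_link, constants):
        series = self.met_series()
        series[1].u = 0.4
        rec = Receptor(id="r", x=100.0, y=0.0)
        chi = build_chi_matrix([straight_link], [rec], series, constants)
        assert not chi.valid[1]
        assert np.isnan(chi.values[0, 0, 1])
        assert np.all(np.isfinite(chi.values[0, 0, [0, 2, 3]]))

    def test_empty_inputs_rejected(self, straight_link, constants):
        with pytest.raises(ValueError):
            build_chi_matrix([], [Receptor(id="r", x=1, y=1)], self.met_series(),
                             constants)
        with pytest.raises(ValueError):
            build_chi_matrix([straight_link], [], self.met_series(), constants)

    def test_long_csv_round_trip(self, straight_link, constants, tmp_path):
        from nearroad.io import read_chi, write_chi

        recs = [Receptor(id="a", x=100.0, y=0.0), Receptor(id="b", x=-60.0, y=50.0)]
        chi = build_chi_matrix([straight_link], recs, self.met_series(), constants)
        write_chi(chi, tmp_path / "chi.csv")
        back = read_chi(tmp_path / "chi.csv")
        assert back.link_ids == chi.link_ids
        assert back.receptor_ids == chi.receptor_ids
        np.testing.assert_allclose(back.values, chi.values, rtol=1e-12)


class TestNormalizedProfile:
    def test_first_value_one_and_scaling(self):
        np.testing.assert_allclose(normalized_profile([10.0, 5.0, 2.0]),
                                   [1.0, 0.5, 0.2])

    def test_zero_first_value_rejected(self):
        with pytest.raises(ValueError):
            normalized_profile([0.0, 1.0])

    def test_very_stable_flatter_than_neutral(self, straight_link, constants):
        """Stable air holds concentrations up with distance: the very
        stable normalized profile dominates the neutral one."""
        dists = np.arange(10.0, 501.0, 10.0)
        profs = {}
        for regime in ("very_stable", "neutral"):
            chi = [chi_at(straight_link, x, 0.0, regime, constants) for x in dists]
            profs[regime] = normalized_profile(chi)
        assert np.all(profs["very_stable"][1:] >= profs["neutral"][1:])
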