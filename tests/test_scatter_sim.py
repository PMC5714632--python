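"""Klein-Nishina physics and the brute-force scatter oracle."""

import numpy as np
import pytest

import kvscatter as kv
from kvscatter.scatter_sim import (
    MEC2_KEV,
    R_E_CM,
    compton_mu,
    kn_differential_cross_section,
    kn_total_cross_section,
    planar_kn_pdf,
    run_photon_mc,
    scattered_energy,
)


class TestKleinNishina:
    def test_forward_limit_is_re_squared(self):
        for e in (10.0, 60.0, 511.0):
            assert kn_differential_cross_section(e, 0.0) == pytest.approx(R_E_CM**2)

    def test_thomson_limit(self):
        """At vanishing energy the Thomson form (r_e^2/2)(1+cos^2) emerges."""
        th = np.linspace(0, np.pi, 7)
        got = kn_differential_cross_section(1e-3, th)
        expected = 0.5 * R_E_CM**2 * (1 + np.cos(th) ** 2)
        np.testing.assert_allclose(got, expected, rtol=1e-4)
        assert kn_differential_cross_section(1e-3, np.pi / 2) == pytest.approx(
            R_E_CM**2 / 2, rel=1e-4)

    def test_pinned_value_100kev_90deg(self):
        """Independent evaluation of the closed form, frozen."""
        alpha = 100.0 / MEC2_KEV
        ratio = 1.0 / (1.0 + alpha)  # 90 deg: 1 - cos = 1
        by_hand = 0.5 * R_E_CM**2 * ratio**2 * (ratio + 1.0 / ratio - 1.0)
        assert by_hand == pytest.approx(2.8661e-26, rel=1e-4)
        assert kn_differential_cross_section(100.0, np.pi / 2) == pytest.approx(by_hand)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            kn_differential_cross_section(-5.0, 0.1)
        with pytest.raises(ValueError):
            kn_differential_cross_section(60.0, 3.5)

    def test_scattered_energy_ordering_and_backscatter(self):
        e = 100.0
        th = np.linspace(0, np.pi, 11)
        ep = scattered_energy(e, th)
        assert np.all(ep <= e + 1e-12)
        alpha = e / MEC2_KEV
        assert ep[-1] == pytest.approx(e / (1 + 2 * alpha))

    def test_total_cross_section_decreases_with_energy(self):
        """Closed form, checked against numerical solid-angle integration."""
        energies = np.array([20.0, 60.0, 100.0, 150.0])
        sigma = kn_total_cross_section(energies)
        assert np.all(np.diff(sigma) < 0)
        th = np.linspace(0, np.pi, 4001)
        for e, s in zip(energies, sigma):
            integrand = kn_differential_cross_section(e, th) * 2 * np.pi * np.sin(th)
            assert np.trapezoid(integrand, th) == pytest.approx(s, rel=1e-5)

    def test_planar_pdf_normalized(self):
        th = np.linspace(-np.pi, np.pi, 8001)
        for e in (30.0, 120.0):
            assert np.trapezoid(planar_kn_pdf(e, th), th) == pytest.approx(1.0, rel=1e-4)


class TestFirstOrderOracle:
    def test_vacuum_gives_zero(self, geo_single, mono60):
        vac = kv.phantoms.Material("vacuum", 0.0, 0.0,
                                   np.array([10.0, 150.0]), np.zeros(2))
        ph = kv.VoxelPhantom(np.zeros((32, 32), int), (4.0, 4.0),
                             (-64.0, -64.0), [vac])
        with pytest.warns(UserWarning, match="no electron"):
            s1 = kv.simulate_first_order_scatter(ph, geo_single, mono60)
        assert np.all(s1.as_array() == 0)

    def test_single_site_closed_form(self, mono60):
        """One electron-bearing, attenuation-free voxel in vacuum: the sum
        has exactly one term, evaluated by hand from fluence x mu_compton
        x area x angular weight."""
        vac = kv.phantoms.Material("vacuum", 0.0, 0.0,
                                   np.array([10.0, 150.0]), np.zeros(2))
        egas = kv.phantoms.Material("electron-gas", 1.0, 1.0,
                                    np.array([10.0, 150.0]), np.zeros(2))
        grid = np.zeros((33, 33), int)
        grid[16, 16] = 1  # 4-mm voxel at the isocenter
        ph = kv.VoxelPhantom(grid, (4.0, 4.0), (-66.0, -66.0), [vac, egas])
        geo = kv.ScanGeometry(1000.0, 500.0, 2.4, 64, angles_deg=[0.0])
        s1 = kv.simulate_first_order_scatter(ph, geo, mono60,
                                             site_downsample=1)[0].pixel_fluence

        src = np.array([1000.0, 0.0])
        i0 = 1.0e5  # open-field photon count per pixel
        k = 40  # an off-axis pixel
        u = (k - 31.5) * 2.4
        pix = np.array([-500.0, u])
        d_in = -src / np.linalg.norm(src)
        d_out = pix - np.array([0.0, 0.0])
        r_out = np.linalg.norm(d_out)
        theta = np.arccos(d_in @ (d_out / r_out))
        e_prime = scattered_energy(60.0, theta)
        mu_c = compton_mu(1.0, 60.0)
        # per-radian source intensity / distance = fluence per cm at the site
        dtheta_src = geo.pixel_angular_widths(src, 0.0)
        i_ang = i0 / dtheta_src[31]  # central column
        phi = i_ang / 100.0  # 1000 mm = 100 cm from source, no attenuation
        events = phi * mu_c * 0.16  # 4 mm x 4 mm site area in cm^2
        cosb = abs(d_out[0]) / r_out
        dtheta_pix = 2.4 * cosb / r_out
        expected = (events * planar_kn_pdf(60.0, theta) * dtheta_pix
                    * e_prime / 100.0)
        assert s1[k] == pytest.approx(float(expected), rel=0.02)

    def test_thin_slab_linear_in_thickness(self, mono60):
        """Optically thin: doubling slab thickness doubles first-order
        scatter at the detector."""
        geo = kv.ScanGeometry(1000.0, 500.0, 2.4, 64, angles_deg=[0.0])
        out = []
        for rows in ((32,), (31, 33)):
            grid = np.zeros((64, 64), int)
            for r in rows:
                grid[r, :] = 1
            ph = kv.VoxelPhantom(grid, (1.0, 1.0), (-32.0, -32.0),
                                 [kv.load_material("air"), kv.load_material("water")])
            s1 = kv.simulate_first_order_scatter(ph, geo, mono60,
                                                 site_downsample=1)
            out.append(s1[0].pixel_fluence[28:36].mean())
        assert out[1] / out[0] == pytest.approx(2.0, rel=0.05)


class TestMonteCarlo:
    def test_vacuum_scores_open_field_only(self, geo_single, mono60):
        vac = kv.phantoms.Material("vacuum", 0.0, 0.0,
                                   np.array([10.0, 150.0]), np.zeros(2))
        ph = kv.VoxelPhantom(np.zeros((16, 16), int), (4.0, 4.0),
                             (-32.0, -32.0), [vac])
        res = run_photon_mc(ph, geo_single, mono60, n_photons=20_000, rng_seed=1)
        assert res.first_order.sum() == 0
        assert res.higher_order.sum() == 0
        assert res.primary.sum() > 0

    def test_fixed_seed_reproducible(self, water_cyl80, geo_single, mono60):
        a = run_photon_mc(water_cyl80, geo_single, mono60, 20_000, rng_seed=5)
        b = run_photon_mc(water_cyl80, geo_single, mono60, 20_000, rng_seed=5)
        np.testing.assert_array_equal(a.first_order, b.first_order)
        np.testing.assert_array_equal(a.higher_order, b.higher_order)

    def test_minimum_photon_count_enforced(self, water_cyl80, geo_single, mono60):
        with pytest.raises(ValueError, match="10"):
            kv.simulate_higher_order_scatter(water_cyl80, geo_single, mono60,
                                             n_photons=100, rng_seed=0)

    def test_mc_first_order_matches_deterministic(self, mono60):
        """Cross-validation of the two scatter realizations on a small
        cylinder: agreement within 3 MC standard errors."""
        geo = kv.ScanGeometry(1000.0, 500.0, 2.4, 64, angles_deg=[0.0])
        ph = kv.make_cylinder_phantom(50.0, (64, 64), 2.0)
        det = kv.simulate_first_order_scatter(ph, geo, mono60,
                                              site_downsample=2)[0].pixel_fluence
        mc = run_photon_mc(ph, geo, mono60, n_photons=100_000, rng_seed=7)
        se = np.maximum(mc.first_order_stderr[0], 1e-9)
        z = (mc.first_order[0] - det) / se
        assert np.abs(z).max() < 3.0


class TestGroundTruthAndSPR:
    def test_whole_equals_sum_of_components(self, water_cyl80, geo_single, mono60):
        truth = kv.ScatterGroundTruth.generate(
            water_cyl80, geo_single, mono60, site_downsample=4,
            n_photons=20_000, rng_seed=3)
        np.testing.assert_allclose(
            truth.whole.as_array(),
            truth.primary.as_array() + truth.first_order.as_array()
            + truth.higher_order.as_array())
        assert np.all(truth.whole.as_array() >= truth.primary.as_array())

    def test_spr_trivial_cases(self, cyl80_primary):
        same = kv.scatter_primary_ratio(cyl80_primary, cyl80_primary)
        assert same.max_ratio == pytest.approx(0.0, abs=1e-12)
        scaled = cyl80_primary.with_fluence(1.6 * cyl80_primary.as_array())
        assert kv.scatter_primary_ratio(scaled, cyl80_primary).max_ratio == (
            pytest.approx(0.6))

    def test_bolus_increases_max_spr(self, mono60):
        """More material in the beam means more scatter per primary."""
        geo = kv.ScanGeometry(1000.0, 500.0, 2.4, 144, angles_deg=[0.0])
        base = kv.make_cylinder_phantom(70.0, (96, 96), 2.0)
        bol = kv.add_bolus(base, 20.0)
        sprs = {}
        for name, ph in (("base", base), ("bolus", bol)):
            p = kv.forward_project_primary(ph, geo, mono60)
            s1 = kv.simulate_first_order_scatter(ph, geo, mono60, site_downsample=4)
            whole = p.with_fluence(p.as_array() + s1.as_array())
            sprs[name] = kv.scatter_primary_ratio(whole, p).max_ratio
        assert sprs["bolus"] > sprs["base"]
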