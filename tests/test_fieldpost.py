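"""Snapshot post-processing operators against closed-form references."""

import numpy as np
import pytest

from shakeflask import (
    FluidSpec,
    Newtonian,
    SyntheticSpec,
    energy_dissipation,
    extract_contact_line,
    generate_field,
    interfacial_area,
    kla_fields,
    shear_rate_fields,
    shear_rate_nonnewtonian,
    strain_rate_fields,
)
from shakeflask.fieldpost import FieldGrid, _lambda1_symmetric


def fluid(eta=0.1, rho=1000.0):
    return FluidSpec(rho=rho, rheology=Newtonian(eta))


def couette(gamma0=10.0, resolution=24):
    grid, _ = generate_field(
        SyntheticSpec(kind="couette", resolution=resolution,
                      params={"gamma0": gamma0})
    )
    return grid


class TestStrainRates:
    def test_couette_closed_form(self):
        """Planar shear u = (g0*z, 0, 0): ||S|| = g0, lambda1 = g0/2."""
        der = strain_rate_fields(couette(10.0))
        np.testing.assert_allclose(der.S_norm, 10.0, rtol=1e-10)
        np.testing.assert_allclose(der.lambda1, 5.0, rtol=1e-10)

    def test_rigid_rotation_strain_free(self):
        grid, _ = generate_field(
            SyntheticSpec(kind="rigid_rotation", params={"omega": 25.0})
        )
        der = strain_rate_fields(grid)
        assert np.max(der.S_norm) < 1e-9
        assert np.max(der.lambda1) < 1e-9

    def test_lambda1_against_characteristic_polynomial(self):
        """Closed-form eigensolver vs polynomial-root oracle, 1000 random
        symmetric tensors, 1e-10 relative to the tensor norm."""
        rng = np.random.default_rng(7)
        n = 1000
        comp = {k: rng.standard_normal(n) for k in
                ("xx", "yy", "zz", "xy", "xz", "yz")}
        lam = _lambda1_symmetric({k: v for k, v in comp.items()})
        s_norm = np.sqrt(
            2 * (comp["xx"] ** 2 + comp["yy"] ** 2 + comp["zz"] ** 2)
            + 4 * (comp["xy"] ** 2 + comp["xz"] ** 2 + comp["yz"] ** 2)
        )
        for i in range(n):
            S = np.array(
                [
                    [comp["xx"][i], comp["xy"][i], comp["xz"][i]],
                    [comp["xy"][i], comp["yy"][i], comp["yz"][i]],
                    [comp["xz"][i], comp["yz"][i], comp["zz"][i]],
                ]
            )
            tr = np.trace(S)
            m2 = (
                S[0, 0] * S[1, 1] - S[0, 1] ** 2
                + S[0, 0] * S[2, 2] - S[0, 2] ** 2
                + S[1, 1] * S[2, 2] - S[1, 2] ** 2
            )
            det = np.linalg.det(S)
            roots = np.roots([1.0, -tr, m2, -det])
            expected = max(np.max(roots.real), 0.0)
            assert abs(lam[i] - expected) <= 1e-10 * s_norm[i]

    def test_traceless_norm_eigenvalue_inequality(self):
        """For traceless S: ||S|| >= sqrt(3)*lambda1, equality for the
        (l, -l/2, -l/2) spectrum."""
        rng = np.random.default_rng(11)
        n = 500
        comp = {k: rng.standard_normal(n) for k in ("xx", "yy", "xy", "xz", "yz")}
        comp["zz"] = -(comp["xx"] + comp["yy"])
        lam = _lambda1_symmetric(comp)
        s_norm = np.sqrt(
            2 * (comp["xx"] ** 2 + comp["yy"] ** 2 + comp["zz"] ** 2)
            + 4 * (comp["xy"] ** 2 + comp["xz"] ** 2 + comp["yz"] ** 2)
        )
        assert np.all(s_norm >= np.sqrt(3.0) * lam - 1e-9 * s_norm)
        # equality case: diag(l, -l/2, -l/2)
        eq = _lambda1_symmetric(
            {"xx": np.array([2.0]), "yy": np.array([-1.0]),
             "zz": np.array([-1.0]), "xy": np.zeros(1), "xz": np.zeros(1),
             "yz": np.zeros(1)}
        )
        assert np.sqrt(2 * (4 + 1 + 1)) == pytest.approx(np.sqrt(3) * eq[0])

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            strain_rate_fields(couette(resolution=2))

    def test_second_order_interior_convergence(self):
        """Central-difference errors on a smooth field shrink ~4x when the
        spacing halves."""
        A, kz, L = 2.0, 2 * np.pi / 0.1, 0.1

        def max_interior_error(n):
            x = (np.arange(n) + 0.5) * L / n
            X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
            grid = FieldGrid(x, x, x, u=A * np.sin(kz * Z),
                             v=np.zeros_like(X), w=np.zeros_like(X),
                             alpha=np.ones_like(X))
            der = strain_rate_fields(grid)
            exact = A * kz * np.abs(np.cos(kz * Z))
            sl = grid.interior()
            return np.max(np.abs(der.S_norm[sl] - exact[sl]))

        e16, e32 = max_interior_error(16), max_interior_error(32)
        ratio = e16 / e32
        assert 3.0 < ratio < 6.0


class TestEnergyDissipation:
    def test_couette_slab(self):
        """Fully liquid Couette: eps = (eta/rho)*g0^2, P/VL = eps*rho."""
        _, summary = energy_dissipation(couette(10.0), fluid(0.1, 1000.0))
        assert summary.eps == pytest.approx(0.01, rel=1e-9)
        assert summary.P_per_V == pytest.approx(10.0, rel=1e-9)

    def test_quiescent_field(self):
        _, summary = energy_dissipation(couette(0.0), fluid())
        assert summary.eps == pytest.approx(0.0, abs=1e-15)

    def test_turbulence_term_additive(self):
        grid = couette(10.0)
        grid.k = np.full(grid.shape, 0.01)
        grid.omega = np.full(grid.shape, 10.0)
        _, summary = energy_dissipation(grid, fluid(0.1, 1000.0))
        assert summary.eps == pytest.approx(0.01 + 0.09 * 10.0 * 0.01, rel=1e-9)

    def test_power_density_is_rho_times_eps(self):
        for gamma0 in (1.0, 30.0):
            _, s = energy_dissipation(couette(gamma0), fluid(0.02, 850.0))
            assert s.P_per_V == pytest.approx(s.eps * 850.0, rel=1e-12)


class TestInterfacialArea:
    def test_planar_ramp_recovers_cross_section(self):
        grid, ref = generate_field(
            SyntheticSpec(kind="slab_interface", resolution=32,
                          params={"liquid_height": 0.05, "thickness": 0.02})
        )
        _, area = interfacial_area(grid)
        assert area == pytest.approx(ref["area"], rel=0.01)

    def test_uniform_alpha_zero_area(self):
        _, area = interfacial_area(couette())
        assert area == pytest.approx(0.0, abs=1e-15)

    def test_diffuse_sphere_area(self):
        """Droplet with r >= 10 cells and >= 4-cell interface: 4*pi*r^2
        within 2%."""
        grid, ref = generate_field(
            SyntheticSpec(kind="droplet", resolution=64, size=0.1,
                          params={"radius": 0.025, "thickness": 0.008})
        )
        _, area = interfacial_area(grid)
        assert area == pytest.approx(ref["area"], rel=0.02)


class TestKlaFields:
    def uniform_eps_interface_grid(self, gamma0=10.0, n=32):
        """Couette velocity (uniform dissipation) + slab interface."""
        grid, ref = generate_field(
            SyntheticSpec(kind="slab_interface", resolution=n,
                          params={"liquid_height": 0.05, "thickness": 0.02})
        )
        Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")[2]
        grid.u = gamma0 * Z
        return grid, ref

    def test_uniform_field_factorization(self):
        """kLa = 0.4*sqrt(DL)*(eps/nu)^(1/4)*A/V for uniform dissipation."""
        grid, ref = self.uniform_eps_interface_grid()
        fl = fluid(0.05, 1000.0)
        DL = 2e-9
        nu = fl.eta / fl.rho
        eps = nu * 10.0**2
        kla_total, _ = kla_fields(grid, fl, DL)
        expected = 0.4 * np.sqrt(DL) * (eps / nu) ** 0.25 * ref["area"] / grid.total_volume
        assert kla_total == pytest.approx(expected, rel=0.01)

    def test_zero_dissipation_gives_zero(self):
        grid, _ = self.uniform_eps_interface_grid(gamma0=0.0)
        kla_total, kla_liquid = kla_fields(grid, fluid(), DL=2e-9)
        assert kla_total == pytest.approx(0.0, abs=1e-15)
        assert kla_liquid == pytest.approx(0.0, abs=1e-15)

    def test_sqrt_DL_scaling(self):
        grid, _ = self.uniform_eps_interface_grid()
        fl = fluid()
        k1, _ = kla_fields(grid, fl, DL=2e-9)
        k2, _ = kla_fields(grid, fl, DL=4e-9)
        assert k2 == pytest.approx(np.sqrt(2) * k1, rel=1e-12)

    def test_liquid_normalization_larger(self):
        grid, _ = self.uniform_eps_interface_grid()
        kla_total, kla_liquid = kla_fields(grid, fluid(), DL=2e-9)
        assert kla_liquid > kla_total  # liquid volume < total volume


class TestShearRateEstimators:
    def test_couette_both_methods(self):
        grid = couette(8.0)
        der = strain_rate_fields(grid)
        _, gm_norm = shear_rate_fields(grid, der, "strain_norm")
        _, gm_eig = shear_rate_fields(grid, der, "eigen")
        assert gm_norm == pytest.approx(8.0, rel=1e-9)
        assert gm_eig == pytest.approx(1.25 * 8.0, rel=1e-9)

    def test_alpha_weighting_restricts_to_liquid(self):
        """Half-liquid domain with z-dependent shear: the mean covers the
        liquid region only."""
        n, L = 32, 0.1
        x = (np.arange(n) + 0.5) * L / n
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        A = 50.0
        grid = FieldGrid(x, x, x, u=A * Z**2, v=np.zeros_like(X),
                         w=np.zeros_like(X),
                         alpha=(Z < L / 2).astype(float))
        der = strain_rate_fields(grid)
        _, gm = shear_rate_fields(grid, der, "strain_norm")
        # expectation uses the same difference scheme (one-sided first order
        # at the boundary cell, central in the interior)
        du = np.gradient(A * x**2, x[1] - x[0], edge_order=1)
        expected = np.mean(du[x < L / 2])
        assert gm == pytest.approx(expected, rel=1e-9)

    def test_unknown_method_rejected(self):
        grid = couette()
        der = strain_rate_fields(grid)
        with pytest.raises(ValueError):
            shear_rate_fields(grid, der, "bogus")


class TestNonNewtonianShearRate:
    def test_fixed_point_equals_eigen_estimator(self):
        """The per-cell power-law iteration converges to 2.5*lambda1."""
        grid = couette(12.0)
        der = strain_rate_fields(grid)
        gamma, iters = shear_rate_nonnewtonian(der, K=0.104, m=0.956)
        np.testing.assert_allclose(gamma, 2.5 * der.lambda1, rtol=1e-8)
        assert iters <= 10  # contraction factor |(m-1)/m| ~ 0.046

    def test_newtonian_index_immediate(self):
        der = strain_rate_fields(couette(5.0))
        gamma, iters = shear_rate_nonnewtonian(der, K=0.05, m=1.0)
        np.testing.assert_allclose(gamma, 2.5 * der.lambda1, rtol=1e-14)
        assert iters == 1

    def test_zero_strain_cells_stay_zero(self):
        der = strain_rate_fields(couette(0.0))
        gamma, _ = shear_rate_nonnewtonian(der, K=0.1, m=0.9)
        assert np.all(gamma == 0.0)

    def test_low_behavior_index_rejected(self):
        der = strain_rate_fields(couette())
        with pytest.raises(ValueError, match="contraction"):
            shear_rate_nonnewtonian(der, K=0.1, m=0.4)


class TestContactLines:
    def annulus(self, **extra):
        params = {"wall_radius": 0.04, "ring_width": 0.015,
                  "liquid_height": 0.02, "thickness": 0.007, "omega": 5.0}
        params.update(extra)
        grid, ref = generate_field(
            SyntheticSpec(kind="annulus", size=(0.1, 0.1, 0.05),
                          resolution=(64, 64, 48), params=params)
        )
        return grid, ref

    def test_static_annulus_constant_height(self):
        grid, ref = self.annulus()
        for cl in extract_contact_line(grid, [0.004, 0.008]):
            assert not np.any(np.isnan(cl.height))
            np.testing.assert_allclose(
                cl.height, ref["contact_height_bulk"], atol=5e-4
            )

    def test_film_rim_reported_at_small_offset(self):
        """A thin wall film reaching higher than the bulk reports its upper
        rim at offsets inside the film."""
        grid, ref = self.annulus(film_width=0.005, film_height=0.035)
        (inside_film,) = extract_contact_line(grid, [0.002])
        np.testing.assert_allclose(inside_film.height, 0.035, atol=2e-3)
        (bulk,) = extract_contact_line(grid, [0.01])
        np.testing.assert_allclose(bulk.height, 0.02, atol=2e-3)

    def test_tilted_plane_sinusoidal_height(self):
        """Liquid under a plane through the axis tilted by phi: height is
        sinusoidal in azimuth with amplitude ~R*tan(phi)."""
        n, L, H = 64, 0.1, 0.08
        x = (np.arange(n) + 0.5) * L / n
        z = (np.arange(n) + 0.5) * H / n
        X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
        cx = cy = L / 2
        phi = np.deg2rad(15.0)
        z0, t = H / 2, 0.01
        surface = z0 + np.tan(phi) * (X - cx)
        alpha = np.clip(0.5 + (surface - Z) / t, 0.0, 1.0)
        R = 0.04
        grid = FieldGrid(x, x, z, u=np.zeros_like(X), v=np.zeros_like(X),
                         w=np.zeros_like(X), alpha=alpha,
                         wall_radius=R, axis_center=(cx, cy))
        (cl,) = extract_contact_line(grid, [0.002])
        r = R - 0.002
        expected = z0 + r * np.tan(phi) * np.cos(np.deg2rad(cl.azimuth))
        np.testing.assert_allclose(cl.height, expected, atol=1.5e-3)
        amplitude = (np.max(cl.height) - np.min(cl.height)) / 2
        assert amplitude == pytest.approx(r * np.tan(phi), rel=0.02)

    def test_all_gas_offset_gives_absent_line(self):
        grid, _ = self.annulus()
        (cl,) = extract_contact_line(grid, [0.03])  # inside the dry core
        assert np.all(np.isnan(cl.height))

    def test_offset_beyond_wall_rejected(self):
        grid, _ = self.annulus()
        with pytest.raises(ValueError):
            extract_contact_line(grid, [0.05])
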