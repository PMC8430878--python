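"""Tests for coefficient assembly, the pressure solve and velocity maps."""

import numpy as np
import pytest

from dcecfm import solver as S
from dcecfm.constants import TissueConstants, TissueParams
from dcecfm.domain import DomainGrid, LABEL_NORMAL, LABEL_TUMOR
from dcecfm.reference import radial_two_region_pressure
from dcecfm.synthetic import ellipsoid_mask


def sphere_domain(radius_mm, shell_mm, h_mm, ktrans=0.2):
    """Two-region spherical domain built directly from geometry."""
    n = int(np.ceil(2 * (radius_mm + shell_mm) / h_mm)) + 3
    center = np.array([n / 2.0 * h_mm] * 3)
    sp = (h_mm,) * 3
    tum = ellipsoid_mask((n, n, n), sp, center, np.array([radius_mm] * 3))
    dil = ellipsoid_mask((n, n, n), sp, center,
                         np.array([radius_mm + shell_mm] * 3))
    labels = np.zeros((n, n, n), np.uint8)
    labels[dil] = LABEL_NORMAL
    labels[tum] = LABEL_TUMOR
    return DomainGrid(labels=labels, spacing_mm=h_mm,
                      ktrans=np.where(tum, ktrans, np.nan), ktrans_mean=ktrans)


def all_tumor_domain(n=10, ktrans=0.2):
    labels = np.full((n, n, n), LABEL_TUMOR, np.uint8)
    return DomainGrid(labels=labels, spacing_mm=1.0,
                      ktrans=np.full((n, n, n), ktrans), ktrans_mean=ktrans)


class TestAssembly:
    def test_uniform_ktrans_source_conductance(self, constants):
        """Uniform Ktrans gives f = 1 and tumor g_v = Lp0*(S/V) = 4e-7."""
        grid = sphere_domain(6.0, 4.0, 1.0)
        coeff = S.assemble_coefficients(grid, constants)
        tum = grid.tumor_mask
        np.testing.assert_allclose(coeff.f[tum], 1.0)
        np.testing.assert_allclose(coeff.g_v[tum], 2e-11 * 2e4)

    def test_ktrans_scaling_linearity(self, constants):
        grid = sphere_domain(6.0, 4.0, 1.0)
        kt = grid.ktrans.copy()
        idx = tuple(np.argwhere(grid.tumor_mask)[0])
        kt[idx] = 2.0 * grid.ktrans_mean
        grid2 = DomainGrid(labels=grid.labels, spacing_mm=1.0, ktrans=kt,
                           ktrans_mean=grid.ktrans_mean)
        coeff = S.assemble_coefficients(grid2, constants)
        assert coeff.g_v[idx] == pytest.approx(2.0 * 2e-11 * 2e4)

    def test_normal_shell_table_lookup(self, constants):
        grid = sphere_domain(6.0, 4.0, 1.0)
        coeff = S.assemble_coefficients(grid, constants)
        nrm = grid.normal_mask
        np.testing.assert_allclose(coeff.g_l[nrm], 1e-7)
        np.testing.assert_allclose(coeff.f[nrm], 1.0)
        np.testing.assert_allclose(coeff.g_v[nrm], 3e-12 * 7e3)
        np.testing.assert_allclose(coeff.kh[nrm], 3.8e-13)

    def test_missing_ktrans_rejected(self, constants):
        grid = sphere_domain(6.0, 4.0, 1.0)
        kt = grid.ktrans.copy()
        kt[tuple(np.argwhere(grid.tumor_mask)[0])] = np.nan
        bad = DomainGrid(labels=grid.labels, spacing_mm=1.0, ktrans=kt,
                         ktrans_mean=grid.ktrans_mean)
        with pytest.raises(ValueError):
            S.assemble_coefficients(bad, constants)

    def test_lp_field_mode(self, constants):
        from dcecfm.kinetics import rescale_lp

        grid = sphere_domain(6.0, 4.0, 1.0)
        rng = np.random.default_rng(3)
        jv = np.where(grid.tumor_mask, rng.lognormal(-9, 0.3, grid.labels.shape), 0)
        field = rescale_lp(jv, grid.tumor_mask)
        coeff = S.assemble_coefficients(grid, constants, "lp_field",
                                        lp_field=field.lp_sv)
        np.testing.assert_allclose(coeff.g_v[grid.tumor_mask],
                                   field.lp_sv[grid.tumor_mask])


class TestSolveIfp:
    def test_all_tumor_equilibrium(self, constants):
        """No sink, uniform source: pressure relaxes to the Starling
        equilibrium p_V - sigma_T (pi_V - pi_i) = 2759.2 Pa everywhere."""
        pf = S.solve_ifp(all_tumor_domain(), constants)
        np.testing.assert_allclose(pf.p, 2759.2, rtol=1e-10)

    def test_pure_hydrostatic_equilibrium(self):
        """sigma_T = 0 removes the oncotic term: p_i = p_V = 2300 Pa."""
        tc = TissueConstants(
            tumor=TissueParams(lp0=2e-11, s_over_v=2e4, lymph_coeff=0.0,
                               kh=1.9e-12, pi_i=3230.0, sigma_t=0.0))
        pf = S.solve_ifp(all_tumor_domain(), tc)
        np.testing.assert_allclose(pf.p, 2300.0, rtol=1e-10)

    def test_singular_without_sources_rejected(self):
        tc = TissueConstants()
        grid = all_tumor_domain()
        with pytest.raises(ValueError):
            S.solve_ifp(grid, tc, scaling_mode="lp_field",
                        lp_field=np.zeros(grid.labels.shape))

    def test_conservation_with_sink(self, sphere_solution):
        assert sphere_solution["pressure"].conservation_ratio < 1e-6

    def test_maximum_principle(self, sphere_solution, constants):
        lo = constants.mixed_equilibrium_pressure("normal")
        hi = constants.equilibrium_pressure("tumor")
        p = sphere_solution["pressure"].p
        assert np.nanmin(p) >= lo * 0.99
        assert np.nanmax(p) <= hi * 1.01

    def test_radial_profile_matches_1d_reference(self, sphere_solution):
        """3D Cartesian solve vs the independent 1D spherical finite-volume
        reference: relative L2 error below 2%."""
        grid = sphere_solution["grid"]
        pf = sphere_solution["pressure"]
        r_ref, p_ref = radial_two_region_pressure(10.0, 10.0,
                                                  sphere_solution["constants"])
        idx = np.argwhere(grid.domain_mask)
        r = np.linalg.norm((idx - sphere_solution["center"]) * grid.spacing_mm,
                           axis=1)
        p3 = pf.p[grid.domain_mask]
        p1 = np.interp(r, r_ref, p_ref)
        assert np.linalg.norm(p3 - p1) / np.linalg.norm(p1) < 0.02

    def test_plateau_for_large_tumor(self, constants):
        """When R*sqrt(Lp(S/V)/K_H) >= 10 the core sits within 1% of the
        tumor Starling equilibrium."""
        grid = sphere_domain(22.0, 8.0, 1.0)
        alpha = 22e-3 * np.sqrt(2e-11 * 2e4 / 1.9e-12)
        assert alpha >= 10.0
        pf = S.solve_ifp(grid, constants)
        c = tuple(np.round(np.argwhere(grid.tumor_mask).mean(axis=0)).astype(int))
        assert abs(pf.p[c] - 2759.2) / 2759.2 < 0.01

    def test_sharp_falloff_at_boundary(self, sphere_solution):
        """More than half of the core-to-far-field pressure drop happens
        within 5 mm of the tumor boundary."""
        grid = sphere_solution["grid"]
        p = sphere_solution["pressure"].p
        c = sphere_solution["center"]
        idx = np.argwhere(grid.domain_mask)
        r = np.linalg.norm((idx - c) * grid.spacing_mm, axis=1)
        vals = p[grid.domain_mask]
        core = vals[r < 3.0].mean()
        far = vals[r > 18.0].mean()
        at_r5 = vals[np.abs(r - 15.0) < 0.5].mean()
        assert (core - at_r5) / (core - far) > 0.5

    def test_grid_convergence(self, constants):
        """Halving the voxel size changes the tumor-mean pressure by < 1%."""
        means = []
        for h in (1.0, 0.5):
            grid = sphere_domain(8.0, 8.0, h)
            pf = S.solve_ifp(grid, constants)
            means.append(pf.p[grid.tumor_mask].mean())
        assert abs(means[1] - means[0]) / means[0] < 0.01


class TestVelocity:
    def test_uniform_pressure_zero_velocity(self, constants):
        grid = all_tumor_domain()
        pf = S.solve_ifp(grid, constants)
        coeff = S.assemble_coefficients(grid, constants)
        vel = S.compute_ifv(pf, coeff.kh, grid.domain_mask)
        np.testing.assert_allclose(vel.magnitude, 0.0, atol=1e-12)

    def test_linear_ramp_hand_computed(self):
        """p = a*x with K_H = 1.9e-12 gives |u| = K_H * a exactly on
        interior voxels (and one-sided edges)."""
        n = 8
        labels = np.full((n, n, n), LABEL_TUMOR, np.uint8)
        grid = DomainGrid(labels=labels, spacing_mm=1.0,
                          ktrans=np.full((n, n, n), 0.1), ktrans_mean=0.1)
        a = 500.0  # Pa per voxel (1 mm)
        x = np.arange(n)[:, None, None] * np.ones((1, n, n))
        pf = S.PressureField(p=a * x, spacing_mm=1.0, residual=0.0,
                             iterations=0, method="manual")
        vel = S.compute_ifv(pf, np.full((n, n, n), 1.9e-12), grid.domain_mask)
        np.testing.assert_allclose(vel.magnitude, 1.9e-12 * a / 1e-3,
                                   rtol=1e-12)

    def test_max_velocity_in_boundary_shell(self, sphere_solution):
        """The Darcy speed peaks in the tumor-rim shell (R +/- 2 voxels)."""
        grid = sphere_solution["grid"]
        vel = sphere_solution["velocity"]
        idx = np.argwhere(grid.domain_mask)
        r = np.linalg.norm((idx - sphere_solution["center"]) * grid.spacing_mm,
                           axis=1)
        mag = vel.magnitude[grid.domain_mask]
        r_at_max = r[np.argmax(mag)]
        assert abs(r_at_max - sphere_solution["radius_mm"]) <= 2.0


class TestSummaries:
    def test_constant_pressure_summary(self, constants):
        grid = all_tumor_domain()
        pf = S.PressureField(p=np.full(grid.labels.shape, 2630.0),
                             spacing_mm=1.0, residual=0.0, iterations=0,
                             method="manual")
        vel = S.compute_ifv(pf, np.full(grid.labels.shape, 1.9e-12),
                            grid.domain_mask)
        summ = S.summarize_fields(pf, vel, grid, label="pre-TX")
        assert summ.mean_ifp_kpa == pytest.approx(2.63)
        assert summ.sd_ifp_kpa == 0.0

    def test_means_match_naive_average(self, sphere_solution):
        grid = sphere_solution["grid"]
        summ = S.summarize_fields(sphere_solution["pressure"],
                                  sphere_solution["velocity"], grid)
        naive_p = float(np.mean(sphere_solution["pressure"].p[grid.tumor_mask]))
        naive_v = float(np.mean(sphere_solution["velocity"].magnitude[grid.tumor_mask]))
        assert summ.mean_ifp_kpa == pytest.approx(naive_p / 1000.0, rel=1e-14)
        assert summ.mean_ifv == pytest.approx(naive_v, rel=1e-14)

    def test_empty_tumor_rejected(self, constants):
        labels = np.full((4, 4, 4), LABEL_NORMAL, np.uint8)
        grid = DomainGrid(labels=labels, spacing_mm=1.0,
                          ktrans=np.full((4, 4, 4), np.nan), ktrans_mean=0.1)
        pf = S.solve_ifp(grid, constants)
        coeff = S.assemble_coefficients(grid, constants)
        vel = S.compute_ifv(pf, coeff.kh, grid.domain_mask)
        with pytest.raises(ValueError):
            S.summarize_fields(pf, vel, grid)
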