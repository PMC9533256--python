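"""Pennes solver: boundary handling, stability, and agreement with the
closed-form Bessel-function solution."""

import numpy as np
import pytest

import braincool as bc


class TestTransient:
    def test_time_zero_is_uniform_initial_condition(self, small_domain):
        fld = bc.solve_transient(small_domain, bc.ProbeSpec(), times=[0.0])[0]
        free = ~fld.probe_mask
        assert np.allclose(fld.temperature[free], 37.0)

    def test_body_temperature_probe_leaves_field_near_37(self, small_domain):
        probe = bc.ProbeSpec(surface_temperature=37.0)
        for fld in bc.solve_transient(small_domain, probe, times=[60.0, 600.0]):
            # only the perfusion-metabolism equilibrium offset remains
            assert np.max(np.abs(fld.temperature - 37.0)) <= 0.35

    def test_probe_surface_and_outer_boundary_values(self, small_cooling_fields):
        fld = small_cooling_fields[-1]
        assert np.allclose(fld.temperature[fld.probe_mask], 15.0)
        assert np.allclose(fld.temperature[-1, :], 37.0)

    def test_discrete_maximum_principle(self, small_cooling_fields, tissue, blood):
        T_eq = bc.equilibrium_temperature(tissue, blood)
        for fld in small_cooling_fields:
            assert fld.temperature.min() >= 15.0 - 1e-9
            assert fld.temperature.max() <= max(T_eq, 37.0) + 0.05

    def test_monotone_cooling_in_time(self, small_cooling_fields):
        for earlier, later in zip(small_cooling_fields, small_cooling_fields[1:]):
            assert np.max(later.temperature - earlier.temperature) <= 1e-4

    def test_bad_times_rejected(self, small_domain):
        with pytest.raises(ValueError):
            bc.solve_transient(small_domain, bc.ProbeSpec(), times=[10.0, 5.0])
        with pytest.raises(ValueError):
            bc.solve_transient(small_domain, bc.ProbeSpec(), times=[-1.0])

    def test_nonconvergence_raises_solver_error(self, small_domain):
        opts = bc.SolverOptions(max_iter=1, tol=1e-14, dt_max=60.0)
        with pytest.raises(bc.SolverError):
            bc.solve_transient(small_domain, bc.ProbeSpec(), times=[60.0],
                               options=opts)


class TestSteady:
    def test_no_probe_relaxes_to_equilibrium(self, tissue, blood):
        dom = bc.SimulationDomain(height=60.0, radius=30.0)
        fld = bc.solve_steady(dom, probe=None, tissue=tissue, blood=blood)
        T_eq = bc.equilibrium_temperature(tissue, blood)
        # uniform up to the (tiny) mismatch between the 37 degC boundary
        # and the perfusion-metabolism equilibrium
        assert np.max(np.abs(fld.temperature - T_eq)) <= 0.01

    def test_steady_matches_long_transient(self, small_domain):
        probe = bc.ProbeSpec()
        f_steady = bc.solve_steady(small_domain, probe)
        f_long = bc.solve_transient(small_domain, probe, times=[3600.0])[0]
        assert np.max(np.abs(f_steady.temperature - f_long.temperature)) <= 0.05

    def test_residual_reported_and_small(self, small_domain):
        fld = bc.solve_steady(small_domain, bc.ProbeSpec())
        assert fld.meta["residual_rel"] <= 1e-8


class TestBesselOracle:
    """Linearized steady solution around an effectively infinite cylinder
    must match the K0 closed form."""

    def test_penetration_length_default(self, tissue, blood):
        lam = bc.penetration_length(tissue, blood, 37.0) * 1e3
        assert lam == pytest.approx(3.9, abs=0.1)

    def test_analytic_profile_limits(self, tissue, blood):
        lam = bc.penetration_length(tissue, blood, 37.0) * 1e3
        assert bc.analytic_cylinder_profile(1.65, 1.65, 15.0) == pytest.approx(15.0)
        far = bc.analytic_cylinder_profile(20 * lam, 1.65, 15.0)
        T_inf = bc.analytic_cylinder_profile(40 * lam, 1.65, 15.0)
        assert far == pytest.approx(T_inf, abs=1e-6)
        with pytest.raises(ValueError):
            bc.analytic_cylinder_profile(1.0, 1.65, 15.0)

    def test_linearized_solver_matches_k0_profile(self):
        dom = bc.SimulationDomain(height=40.0, radius=80.0,
                                  axial_boundary="neumann", h_fine=0.25)
        probe = bc.ProbeSpec(surface_temperature=15.0, tip_length=40.0)
        fld = bc.PennesSolver(dom, probe,
                              options=bc.SolverOptions(linearize_at=37.0)
                              ).solve_steady()
        r = np.linspace(1.65, 15.0, 60)
        numeric = fld.radial_profile(r)
        analytic = bc.analytic_cylinder_profile(r, 1.65, 15.0, frozen_T=37.0)
        drop = 37.0 - 15.0
        assert np.max(np.abs(numeric - analytic)) / drop < 0.01


class TestGeometry:
    def test_equal_volume_cylinder_radius(self):
        dom = bc.SimulationDomain()
        assert np.pi * dom.outer_radius ** 2 * dom.height == pytest.approx(8.0e6)

    def test_probe_must_fit(self):
        with pytest.raises(bc.GeometryError):
            bc.PennesSolver(bc.SimulationDomain(height=20.0, radius=40.0),
                            bc.ProbeSpec(tip_length=25.0))

    def test_shell_requires_axisymmetric(self):
        dom = bc.SimulationDomain(mode="cartesian3d", extent=(40., 40., 60.))
        probe = bc.ProbeSpec(shell=bc.ShellSpec())
        with pytest.raises(NotImplementedError):
            bc.PennesSolver(dom, probe)

    def test_invalid_probe_and_domain_specs(self):
        with pytest.raises(ValueError):
            bc.ProbeSpec(outer_diameter=-1.0)
        with pytest.raises(ValueError):
            bc.ProbeSpec(shell=bc.ShellSpec(thickness=2.0))
        with pytest.raises(ValueError):
            bc.SimulationDomain(mode="spherical")


class TestShellProbe:
    def test_shell_probe_surface_between_internal_and_tissue(self):
        dom = bc.SimulationDomain(height=80.0, radius=40.0, h_fine=0.25)
        shell = bc.ShellSpec(thickness=0.5, internal_temperature=0.0)
        probe = bc.ProbeSpec(shell=shell)
        fld = bc.PennesSolver(dom, probe).solve_steady()
        # the highly conductive sapphire band warms only slightly across its
        # thickness, and the tissue-facing surface must sit between the
        # internal coolant temperature and the far field
        surf = fld.radial_profile(np.array([1.65]))[0]
        assert 0.0 < surf < 37.0


class TestCartesian3D:
    def test_midheight_profile_matches_axisymmetric(self):
        probe = bc.ProbeSpec()
        opts = bc.SolverOptions(dt_max=10.0)
        f_axi = bc.PennesSolver(bc.SimulationDomain(height=80.0, radius=40.0),
                                probe, options=opts).solve_transient([136.0])[0]
        dom3 = bc.SimulationDomain(mode="cartesian3d", extent=(80., 80., 80.),
                                   h_fine3=0.4)
        f_3d = bc.PennesSolver(dom3, probe, options=opts).solve_transient([136.0])[0]
        r = np.linspace(4.0, 15.0, 23)
        drop = 37.0 - 15.0
        err = np.max(np.abs(f_axi.radial_profile(r) - f_3d.radial_profile(r)))
        assert err / drop < 0.02
        # volumetric integration agreement between the two geometries
        for thr in (36.0, 34.0):
            va = bc.volume_below(f_axi, thr)
            v3 = bc.volume_below(f_3d, thr)
            assert abs(va - v3) / va < 0.03
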