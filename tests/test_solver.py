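"""SIMPLE solver checks against the plane-Poiseuille closed form and its
conservation/linearity/determinism contracts."""

import numpy as np
import pytest

from hemocoherence.geometry import VesselSegment, mesh_vessel
from hemocoherence.solver import (
    BoundaryConditions,
    ConvergenceError,
    FluidProperties,
    NumericsConfig,
    analytic_poiseuille_dp,
    compute_pressure_difference,
    compute_section_flux,
    solve_flow,
)

UM = 1e-6
MU = FluidProperties().dynamic_viscosity


def _solve(h, L, U, na=48, nt=12, **kw):
    mesh = mesh_vessel(VesselSegment.straight(h, L, U), na, nt)
    return solve_flow(mesh, bc=BoundaryConditions(inlet_velocity=U * UM), **kw)


def _developed_dp_error(sol, h, U):
    """Relative error of dp over the downstream 80 percent vs Poiseuille."""
    dp = sol.pressure_difference(0.2, 1.0)
    L_meas = abs(sol.section_x(1.0) - sol.section_x(0.2))
    return dp / analytic_poiseuille_dp(U * UM, h * UM, L_meas, MU) - 1.0


class TestAnalyticOracle:
    def test_reference_value(self):
        dp = analytic_poiseuille_dp(15e-6, 17.2e-6, 137.3e-6, 3.36e-3)
        assert dp == pytest.approx(0.281, abs=0.001)

    def test_scalings(self):
        base = analytic_poiseuille_dp(1e-5, 1e-5, 1e-4, 3e-3)
        assert analytic_poiseuille_dp(1e-5, 1e-5, 2e-4, 3e-3) == pytest.approx(2 * base)
        assert analytic_poiseuille_dp(1e-5, 2e-5, 1e-4, 3e-3) == pytest.approx(base / 4)

    def test_wider_channel_case_in_reported_band(self):
        dp = analytic_poiseuille_dp(10e-6, 25e-6, 100e-6, MU)
        assert dp == pytest.approx(0.065, abs=0.002)
        assert 0.02 <= dp <= 0.1


class TestBaseCase:
    def test_converged_to_tolerance(self, base_solution):
        sol = base_solution
        assert sol.converged
        for key in ("u_momentum", "v_momentum", "continuity"):
            assert sol.residuals[key][-1] <= 1e-6 * 1.0001

    def test_fully_developed_centerline_velocity(self, base_solution):
        u = base_solution.u
        ni, nj = u.shape
        profile = u[int(0.9 * ni)]
        # cell centres straddle the axis: the analytic parabola at +/- dy/2
        expected = 1.5 * 15 * UM * (1 - (1 / nj) ** 2)
        assert profile.max() == pytest.approx(expected, rel=0.01)

    def test_no_slip_wall_layer(self, base_solution):
        u = base_solution.u
        ni, nj = u.shape
        profile = u[int(0.9 * ni)]
        # wall-adjacent cell centre sits at delta/2; parabola value there
        wall_cell = 1.5 * 15 * UM * (1 - (1 - 1 / nj) ** 2)
        assert profile[0] == pytest.approx(wall_cell, rel=0.05)
        assert profile[0] < 0.12 * profile.max()

    def test_dp_matches_poiseuille(self, base_solution):
        assert abs(_developed_dp_error(base_solution, 17.2, 15)) < 0.02

    def test_plug_inlet_flux_is_exact(self, base_solution):
        q = compute_section_flux(base_solution, 0)
        assert q == pytest.approx(15 * UM * 17.2 * UM, rel=1e-12)

    def test_mass_conserved_at_every_section(self, base_solution):
        sol = base_solution
        assert sol.mass_imbalance <= 1e-3
        q_in = sol.section_flux(0)
        for frac in (0.25, 0.5, 0.75, 1.0):
            assert sol.section_flux(frac) == pytest.approx(q_in, rel=1e-3)

    def test_reynolds_is_creeping(self, base_solution):
        assert base_solution.reynolds == pytest.approx(
            15 * UM * 17.2 * UM / 3.2e-6, rel=1e-6
        )
        assert base_solution.reynolds < 1e-3


class TestContracts:
    def test_stokes_linearity(self):
        base = _solve(17.2, 137.3, 15)
        dp0 = base.pressure_difference(0.2, 1.0)
        for alpha in (0.5, 2.0, 4.0):
            sol = _solve(17.2, 137.3, 15 * alpha)
            ratio = sol.pressure_difference(0.2, 1.0) / dp0
            assert ratio == pytest.approx(alpha, rel=0.01)

    def test_grid_convergence(self):
        errs = [
            abs(_developed_dp_error(_solve(17.2, 137.3, 15, na, nt), 17.2, 15))
            for na, nt in ((40, 8), (80, 16), (160, 32))
        ]
        assert errs[1] < errs[0]
        assert errs[2] < errs[1]

    def test_bit_identical_reruns(self):
        s1 = _solve(17.2, 137.3, 15)
        s2 = _solve(17.2, 137.3, 15)
        for key in s1.residuals:
            np.testing.assert_array_equal(s1.residuals[key], s2.residuals[key])
        np.testing.assert_array_equal(s1.p, s2.p)

    def test_zero_length_section_difference(self, base_solution):
        assert compute_pressure_difference(base_solution, 0.5, 0.5) == 0.0

    def test_unconverged_solution_refuses_measurement(self):
        sol = _solve(
            17.2, 137.3, 15,
            numerics=NumericsConfig(max_outer_iterations=3),
            raise_on_failure=False,
        )
        assert not sol.converged
        with pytest.raises(ConvergenceError):
            sol.pressure_difference()

    def test_nonconvergence_raises_with_history(self):
        with pytest.raises(ConvergenceError) as err:
            _solve(17.2, 137.3, 15, numerics=NumericsConfig(max_outer_iterations=3))
        assert len(err.value.residuals["u_momentum"]) == 3

    def test_high_reynolds_warns(self):
        with pytest.warns(UserWarning, match="laminar"):
            _solve(
                17.2, 137.3, 2.5e7,  # ~25 m/s -> Re above 100
                numerics=NumericsConfig(max_outer_iterations=2),
                raise_on_failure=False,
            )

    def test_field_export(self, tmp_path, base_solution):
        path = tmp_path / "field.vtk"
        base_solution.to_vtk(path)
        text = path.read_text()
        for name in ("u", "v", "p", "boundary_tag"):
            assert f"SCALARS {name} double 1" in text
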