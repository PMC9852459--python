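"""Full-wave solver: free-space exactness, windows, hot spots, errors."""

import numpy as np
import pytest
from scipy.special import erf

from adipoptics.fixtures import layered_cylinder_field
from adipoptics.fullwave import (
    BeamSpec,
    ConvergenceError,
    HotspotSet,
    find_hotspots,
    incident_field,
    solve_forward,
    transmitted_fraction,
)
from adipoptics.geometry import IndexField

LAM = 0.93


def uniform_grid(n=1.36, depth=140.0, width=80.0, dx=0.0637):
    nz, nx = int(depth / dx), int(width / dx)
    arr = np.full((nz, nx), n)
    return IndexField(n=arr, spacing=dx, origin=(0.0, -nx // 2 * dx))


class TestIncidentField:
    def test_angular_spectrum_matches_gaussian_beam_width(self):
        grid = uniform_grid()
        beam = BeamSpec()
        e = incident_field(grid, beam, 1.36)
        x = grid.x
        for z_target, iz in [(0.0, grid.iz(0.0)), (120.0, grid.iz(120.0))]:
            I = np.abs(e[iz]) ** 2
            w_meas = np.sqrt(4 * np.sum(x**2 * I) / np.sum(I))
            zr = np.pi * 10.0**2 * 1.36 / LAM
            w_theory = 10.0 * np.sqrt(1 + (z_target / zr) ** 2)
            assert w_meas == pytest.approx(w_theory, rel=5e-3)

    def test_lateral_offset_shifts_the_axis(self):
        grid = uniform_grid(width=100.0)
        e = incident_field(grid, BeamSpec(lateral_offset=15.0), 1.36)
        I = np.abs(e[grid.iz(0.0)]) ** 2
        assert grid.x[np.argmax(I)] == pytest.approx(15.0, abs=grid.spacing)

    def test_plane_wave_is_uniform_across_x(self):
        grid = uniform_grid(depth=10.0, width=20.0, dx=0.1)
        e = incident_field(grid, BeamSpec(waist_radius=None), 1.36)
        assert np.abs(e).std() < 1e-6


@pytest.fixture(scope="module")
def solution():
    grid = uniform_grid()
    return solve_forward(grid, BeamSpec(), tol=1e-4)


class TestUniformMedium:
    def test_total_field_matches_free_space_beam(self, solution):
        err = np.linalg.norm(solution.amplitude - solution.incident) / np.linalg.norm(
            solution.incident
        )
        assert err < 0.01

    def test_window_transmittance_matches_erf_closed_form(self, solution):
        res = transmitted_fraction(solution, z_plane=120.0)
        zr = np.pi * 10.0**2 * 1.36 / LAM
        w = 10.0 * np.sqrt(1 + (120.0 / zr) ** 2)
        expected = erf(np.sqrt(2.0) * 10.0 / w)
        assert res.T == pytest.approx(expected, abs=0.01)
        assert res.T == pytest.approx(0.95, abs=0.01)

    def test_single_hotspot_is_the_beam_itself(self, solution):
        spots = find_hotspots(solution, 120.0, min_prominence=0.05)
        assert len(spots) == 1
        assert spots.positions[0] == pytest.approx(0.0, abs=0.1)

    def test_window_outside_domain_rejected(self, solution):
        with pytest.raises(ValueError, match="window"):
            transmitted_fraction(solution, z_plane=120.0, window_center=50.0)
        with pytest.raises(ValueError, match="outside"):
            transmitted_fraction(solution, z_plane=500.0)


class TestSolverContracts:
    def test_cylinder_oracle_quick(self):
        # scaled-down layered-cylinder benchmark (full gate in acceptance)
        dx = LAM / (12 * 1.46)
        half = 7.0
        n_pts = int(2 * half / dx)
        x = -half + np.arange(n_pts) * dx
        X, Z = np.meshgrid(x, x)
        r = np.hypot(X, Z)
        n = np.where(r <= 2.5, 1.46, 1.36)
        grid = IndexField(n=n, spacing=dx, origin=(x[0], x[0]))
        sol = solve_forward(grid, BeamSpec(waist_radius=None), tol=1e-5)
        m = int(2.0 / dx)
        ana = layered_cylinder_field([2.5], [1.46], 1.36, LAM, x[m:-m:2], x[m:-m:2])
        num = (sol.amplitude - sol.incident)[m:-m:2, m:-m:2]
        err = np.linalg.norm(num - ana["scattered"]) / np.linalg.norm(ana["scattered"])
        assert err < 0.03

    def test_exhausted_iteration_budget_reports_history(self):
        grid = uniform_grid(depth=30.0, width=30.0, dx=0.08)
        grid.n[100:150, 100:150] = 1.46
        with pytest.raises(ConvergenceError) as exc:
            solve_forward(grid, BeamSpec(), max_iter=10, tol=1e-10)
        assert len(exc.value.residual_history) > 0

    def test_non_2d_field_rejected(self):
        bad = IndexField(n=np.ones(10), spacing=0.1, origin=(0.0, 0.0))
        with pytest.raises(ValueError, match="2-D"):
            solve_forward(bad, BeamSpec())

    def test_subunity_index_rejected(self):
        grid = uniform_grid(depth=10.0, width=10.0, dx=0.1)
        grid.n[0, 0] = 0.5
        with pytest.raises(ValueError, match=">= 1"):
            solve_forward(grid, BeamSpec())


class TestLatticePhenomenology:
    def test_photonic_jet_exceeds_incident_peak(self, two_layer_center_solution):
        # sharp local focusing: the on-axis intensity just past the cells
        # exceeds the incident beam's peak intensity
        sol, _, lattice = two_layer_center_solution
        grid = sol.grid
        band = (grid.z > lattice.thickness - 10.0) & (
            grid.z < lattice.thickness + 15.0
        )
        jet = np.abs(sol.amplitude[band]) ** 2
        assert jet.max() > np.abs(sol.incident).max() ** 2

    def test_mirror_symmetry_of_centered_incidence(self, two_layer_center_solution):
        sol, _, lattice = two_layer_center_solution
        grid = sol.grid
        iz = grid.iz(lattice.thickness + 1.0)
        profile = np.abs(sol.amplitude[iz]) ** 2
        ix0 = grid.ix(0.0)
        m = min(ix0, len(profile) - 1 - ix0)
        left = profile[ix0 - m : ix0]
        right = profile[ix0 + 1 : ix0 + m + 1][::-1]
        asym = np.abs(left - right).sum() / (left + right).sum()
        assert asym < 0.01

    def test_offset_incidence_breaks_symmetry(self, two_layer_offset_solution):
        sol, _, lattice = two_layer_offset_solution
        grid = sol.grid
        iz = grid.iz(lattice.thickness + 1.0)
        profile = np.abs(sol.amplitude[iz]) ** 2
        D = lattice.cell.outer_diameter
        ix0 = grid.ix(D / 4)  # beam axis
        m = min(ix0, len(profile) - 1 - ix0)
        left = profile[ix0 - m : ix0].sum()
        right = profile[ix0 + 1 : ix0 + m + 1].sum()
        assert abs(left - right) / (left + right) > 0.05
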