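"""OCT synthesis: split-step propagation, reflectance, scan assembly."""

import numpy as np
import pytest

from adipoptics.geometry import IndexField, build_lattice, rasterize
from adipoptics import oct as om

LAM = 0.93
K_VAC = 2 * np.pi / LAM


def uniform_field(n=1.40, depth=120.0, dx=0.4, nx=512):
    arr = np.full((int(depth / dx) + 1, nx), n)
    return IndexField(n=arr, spacing=dx, origin=(0.0, -nx // 2 * dx))


class TestSplitStepPropagation:
    def test_gaussian_spreading_matches_closed_form(self):
        f = uniform_field()
        x = f.x
        w0 = 6.0
        e0 = np.exp(-(x**2) / w0**2).astype(np.complex64)
        stack = om.propagate_split_step(e0, f, K_VAC, use_absorber=False)
        I = np.abs(stack[-1]) ** 2
        w_meas = np.sqrt(4 * np.sum(x**2 * I) / np.sum(I))
        zr = np.pi * w0**2 / (LAM / 1.40)
        w_theory = w0 * np.sqrt(1 + (120.0 / zr) ** 2)
        assert w_meas == pytest.approx(w_theory, rel=5e-3)

    def test_power_conserved_in_lossless_medium(self):
        f = uniform_field()
        x = f.x
        e0 = np.exp(-(x**2) / 10.0**2).astype(np.complex64)
        stack = om.propagate_split_step(e0, f, K_VAC, use_absorber=False)
        p = np.sum(np.abs(stack) ** 2, axis=1)
        assert np.abs(p / p[0] - 1).max() < 5e-3

    def test_tilted_phase_walks_off_at_ray_angle(self):
        f = uniform_field(depth=60.0)
        x = f.x
        theta = np.radians(5.0)
        kx0 = K_VAC * 1.40 * np.sin(theta)
        e0 = (np.exp(-(x**2) / 8.0**2) * np.exp(1j * kx0 * x)).astype(np.complex64)
        stack = om.propagate_split_step(e0, f, K_VAC, use_absorber=False)
        I = np.abs(stack[-1]) ** 2
        centroid = np.sum(x * I) / np.sum(I)
        assert centroid == pytest.approx(60.0 * np.tan(theta), abs=f.spacing)

    def test_nyquist_energy_warns(self):
        f = uniform_field(depth=2.0, nx=128)
        rng = np.random.default_rng(0)
        noisy = rng.normal(size=128).astype(np.complex64)
        with pytest.warns(UserWarning, match="Nyquist"):
            om.propagate_split_step(noisy, f, K_VAC)


class TestLocalReflectance:
    def test_homogeneous_medium_reflects_nothing(self):
        rmap = om.local_reflectance(uniform_field())
        assert np.all(rmap.r == 0)

    def test_sharp_interface_equals_fresnel(self):
        f = uniform_field(n=1.36, depth=40.0)
        f.n[f.iz(20.0):, :] = 1.46
        rmap = om.local_reflectance(f)
        fresnel = (1.36 - 1.46) / (1.36 + 1.46)
        assert rmap.r.sum(axis=0) == pytest.approx(fresnel, rel=1e-9)

    def test_soft_boundary_sum_converges_to_fresnel(self):
        # a blurred interface reflects the same summed amplitude
        f = uniform_field(n=1.36, depth=40.0, dx=0.1)
        from scipy.special import expit

        z = f.z
        f.n[:] = 1.36 + 0.10 * expit((z[:, None] - 20.0) / 0.25)
        total = om.local_reflectance(f).r.sum(axis=0)
        fresnel = (1.36 - 1.46) / (1.36 + 1.46)
        assert np.all(np.abs(total / fresnel - 1) < 0.05)

    def test_cell_fragment_reflects_only_from_cell_boundaries(self):
        lat = build_lattice(n_layers=2, cells_per_layer=3)
        field = rasterize(lat, 0.4, membrane="omit", softness=0.5)
        rmap = om.local_reflectance(field)
        power = rmap.r**2
        # distance of every pixel to the nearest shell surface
        z = field.z[:-1]
        x = field.x
        Z, X = np.meshgrid(z, x, indexing="ij")
        dist = np.full_like(power, np.inf)
        radii, _ = lat.cell.shells()
        for cx, cz in lat.cell_centers:
            d = np.hypot(Z - cz, X - cx)
            for R in radii[:2]:  # membrane omitted in the raster
                dist = np.minimum(dist, np.abs(d - R))
        near = dist <= 2.0  # within the soft-boundary blur, um
        assert power[near].sum() > 0.99 * power.sum()
        # a mid-cell equatorial slab sees no reflection at the cell center
        layer = rmap.layer_map(lat.cell.outer_diameter / 2, 4.0)
        assert layer[field.ix(0.0)] == 0.0
        assert layer.max() > 0.0


class TestSourceSpectrum:
    def test_air_psf_fwhm_matches_nominal_resolution(self):
        src = om.OctSource()
        assert om.axial_psf_fwhm_air(src) == pytest.approx(6.2, abs=0.3)

    @pytest.mark.parametrize(
        "index, expected", [(1.47, 4.2), (1.0, 6.2), (1.44, 4.31)]
    )
    def test_in_tissue_resolution_is_quotient(self, index, expected):
        src = om.OctSource()
        assert om.calibrate_axial_resolution(src, index) == pytest.approx(
            expected, abs=0.02
        )

    def test_verification_against_synthesized_psf(self):
        src = om.OctSource()
        om.calibrate_axial_resolution(src, 1.44, verify=True)

    def test_inconsistent_beam_geometry_warns(self):
        with pytest.warns(UserWarning, match="Gaussian-beam"):
            om.OctSource(surface_beam_diameter=30.0)


class TestAscanSynthesis:
    def test_uniform_medium_has_no_interior_peaks(self):
        scan = om.synthesize_ascan(uniform_field(n=1.36, nx=256), om.OctSource())
        z, W = scan.depth_axis, scan.W
        surface = W[z < 5].max()
        interior = W[(z > 15) & (z < 160)].max()
        assert interior < 0.01 * surface

    def test_buried_interface_peak_at_optical_depth(self):
        f = uniform_field(n=1.36, depth=100.0, nx=256)
        f.n[f.iz(40.0):, :] = 1.46
        scan = om.synthesize_ascan(f, om.OctSource())
        z, W = scan.depth_axis, scan.W
        sel = z > 15
        peak_depth = z[sel][np.argmax(W[sel])]
        assert peak_depth == pytest.approx(40 * 1.36, abs=om.OctSource().axial_resolution_air)

    def test_fresnel_scaling_between_interface_strengths(self):
        # doubling the index step quadruples the echo energy
        src = om.OctSource(
            focus_beam_diameter=60.0, surface_beam_diameter=60.0, focus_depth=0.0
        )
        peaks = {}
        for step in (0.05, 0.10):
            f = uniform_field(n=1.36, depth=100.0, nx=256)
            f.n[f.iz(40.0):, :] = 1.36 + step
            scan = om.synthesize_ascan(f, src)
            z, W = scan.depth_axis, scan.W
            ratio = 10**W - 1  # back to W_oct / W_oct(0)
            peaks[step] = ratio[np.abs(z - 40 * 1.36) < 8].max()
        assert peaks[0.10] / peaks[0.05] == pytest.approx(4.0, rel=0.1)

    def test_absolute_fresnel_energy_against_surface_echo(self):
        src = om.OctSource(
            focus_beam_diameter=60.0, surface_beam_diameter=60.0, focus_depth=0.0
        )
        f = uniform_field(n=1.36, depth=100.0, nx=512)
        f.n[f.iz(40.0):, :] = 1.46
        scan = om.synthesize_ascan(f, src)
        z, W = scan.depth_axis, scan.W
        ratio = 10**W - 1
        measured = ratio[np.abs(z - 40 * 1.36) < 8].max()  # surface peak == 1
        expected = ((0.10 / 2.82) ** 2) / ((0.36 / 2.36) ** 2)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            om.synthesize_ascan(uniform_field(nx=128), om.OctSource(), n_trials=0)

    def test_seeded_scans_are_bit_identical(self):
        lat = build_lattice(
            n_layers=2, cells_per_layer=3, jitter_fraction=0.2, seed=0
        )
        src = om.OctSource(n_spectral_samples=32)
        a = om.synthesize_ascan(lat, src, n_trials=2, seed=42, grid_spacing=0.5)
        b = om.synthesize_ascan(lat, src, n_trials=2, seed=42, grid_spacing=0.5)
        np.testing.assert_array_equal(a.W, b.W)
        c = om.synthesize_ascan(lat, src, n_trials=2, seed=43, grid_spacing=0.5)
        assert not np.array_equal(a.W, c.W)

    def test_ensemble_averaging_shrinks_trial_variance(self):
        lat = build_lattice(
            n_layers=2, cells_per_layer=3, jitter_fraction=0.2, seed=0
        )
        src = om.OctSource(n_spectral_samples=32)

        def spread(n_trials, seeds):
            vals = []
            for s in seeds:
                scan = om.synthesize_ascan(
                    lat, src, n_trials=n_trials, seed=s, grid_spacing=0.5
                )
                z = scan.depth_axis
                vals.append(scan.W[(z > 10) & (z < 70)].mean())
            return np.std(vals)

        assert spread(4, range(6)) < spread(1, range(6))


class TestScanRaster:
    def test_bscan_stacks_ascans_at_positions(self):
        f = uniform_field(n=1.36, depth=50.0, nx=256)
        xs = np.array([-10.0, 0.0, 10.0])
        scan = om.scan_raster(f, om.OctSource(n_spectral_samples=32), xs)
        assert scan.kind == "B"
        assert scan.W.shape == (len(scan.depth_axis), 3)

    def test_positions_outside_fragment_listed_in_error(self):
        f = uniform_field(nx=128)
        with pytest.raises(ValueError, match="99"):
            om.scan_raster(f, om.OctSource(), np.array([0.0, 99.0]))

    def test_uniform_cscan_is_spatially_constant(self):
        f = uniform_field(n=1.36, depth=60.0, nx=192)
        xs = np.linspace(-6, 6, 5)
        scan = om.scan_raster(
            f,
            om.OctSource(n_spectral_samples=32),
            (xs, xs.copy()),
            c_scan_depth=30.0,
        )
        assert scan.kind == "C"
        assert scan.W.shape == (5, 5)
        assert scan.W.std() / scan.W.mean() < 0.02


class TestBscanPeriodicity:
    def test_regular_lattice_bscan_is_laterally_periodic(self):
        lat = build_lattice(n_layers=3, cells_per_layer=4, n_ISF=1.36)
        D = lat.cell.outer_diameter
        src = om.OctSource(n_spectral_samples=48)
        step = D / 10
        xs = np.arange(-1.5 * D, 1.5 * D + step / 2, step)
        scan = om.scan_raster(lat, src, xs, grid_spacing=0.5)
        z = scan.depth_axis
        profile = scan.W[(z > 10) & (z < 3 * D * 1.5), :].mean(axis=0)
        # shift by one cell diameter (10 samples) and correlate
        a, b = profile[:-10], profile[10:]
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.5
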