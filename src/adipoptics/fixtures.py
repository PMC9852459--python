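"""Seeded generators of benchmark inputs and independent analytic oracles.

Everything a test needs is generated at run time from parameters and
seeds: no binary fixtures are stored.  The layered-cylinder scattering
series implemented here is the independent full-wave oracle — it shares
no code with the Born-series solver it validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp, yv, yvp

from .geometry import CellModel, build_lattice

__all__ = [
    "FixtureCase",
    "layered_cylinder_coefficients",
    "layered_cylinder_field",
    "single_cylinder_case",
    "lattice_suite",
    "synth_bscan",
]


@dataclass
class FixtureCase:
    """One generated benchmark: inputs, closed-form expectations, seed."""

    name: str
    inputs: dict[str, Any]
    expected: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


# ----------------------------------------------------------------------
# Analytic scattering by a multilayered infinite cylinder (TE, normal
# incidence).  The out-of-plane field E_z satisfies the scalar Helmholtz
# equation with E and dE/dr continuous across every interface, so the
# classical Bessel/Hankel series is Maxwell-exact in 2-D.
# ----------------------------------------------------------------------


def layered_cylinder_coefficients(
    radii: Sequence[float],
    indices: Sequence[float],
    n_out: float,
    wavelength: float,
    m_max: int | None = None,
    tail_tol: float = 1e-6,
):
    """Per-order expansion coefficients for a layered cylinder.

    Parameters
    ----------
    radii : ascending interface radii, um (len R).
    indices : refractive index of each internal region, inner to outer
        (len R; region j spans radii[j-1] < r <= radii[j]).
    n_out : embedding-medium index.
    wavelength : vacuum wavelength, um.
    m_max : angular-order cap (default: Wiscombe-style
        ``x + 4.05 x^(1/3) + 15`` with x the outer size parameter).
    tail_tol : required smallness of the last scattering coefficient
        relative to the largest one; violation raises.

    Returns
    -------
    (inner, c) where ``c[m]`` is the scattered Hankel coefficient for a
    unit-amplitude incident ``J_m`` and ``inner[m]`` lists the
    ``(a_j, b_j)`` Bessel coefficients of every internal region.
    """
    radii = np.asarray(radii, dtype=float)
    indices = np.asarray(indices, dtype=float)
    if len(radii) != len(indices):
        raise ValueError("radii and indices must have the same length")
    if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ValueError("radii must be positive and strictly ascending")
    k0 = 2.0 * np.pi / wavelength
    ks = np.concatenate([indices, [n_out]]) * k0
    R = len(radii)
    x = ks[-1] * radii[-1]
    if m_max is None:
        m_max = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 15))

    n_unknown = 2 * R  # a0, (a_j, b_j) for j=1..R-1, c
    inner_coeffs = []
    c = np.zeros(m_max + 1, dtype=complex)
    for m in range(m_max + 1):
        A = np.zeros((n_unknown, n_unknown), dtype=complex)
        rhs = np.zeros(n_unknown, dtype=complex)

        def col_of(region: int) -> tuple[int, int | None]:
            # column indices of (J, Y) coefficients for internal region
            if region == 0:
                return 0, None
            return 2 * region - 1, 2 * region

        row = 0
        for i in range(R):  # interface i between region i and region i+1
            r = radii[i]
            ki, ko = ks[i], ks[i + 1]
            ji, yi = jv(m, ki * r), yv(m, ki * r)
            dji, dyi = ki * jvp(m, ki * r), ki * yvp(m, ki * r)
            cj, cy = col_of(i)
            A[row, cj] = ji
            A[row + 1, cj] = dji
            if cy is not None:
                A[row, cy] = yi
                A[row + 1, cy] = dyi
            if i < R - 1:
                jo, yo = jv(m, ko * r), yv(m, ko * r)
                djo, dyo = ko * jvp(m, ko * r), ko * yvp(m, ko * r)
                oj, oy = col_of(i + 1)
                A[row, oj] = -jo
                A[row + 1, oj] = -djo
                A[row, oy] = -yo
                A[row + 1, oy] = -dyo
            else:  # outermost interface: incident J + scattered Hankel
                A[row, -1] = -hankel1(m, ko * r)
                A[row + 1, -1] = -ko * h1vp(m, ko * r)
                rhs[row] = jv(m, ko * r)
                rhs[row + 1] = ko * jvp(m, ko * r)
            row += 2

        # column equilibration keeps Y_m growth from wrecking conditioning
        scale = np.max(np.abs(A), axis=0)
        scale[scale == 0] = 1.0
        sol = np.linalg.solve(A / scale, rhs) / scale
        c[m] = sol[-1]
        inner_coeffs.append(
            [(sol[col_of(j)[0]], sol[col_of(j)[1]] if j else 0.0) for j in range(R)]
        )

    cmax = np.abs(c).max()
    if cmax > 0 and np.abs(c[-1]) > tail_tol * cmax:
        raise RuntimeError(
            f"layered-cylinder series not converged at order {m_max}: "
            f"|c_M|/|c|_max = {np.abs(c[-1]) / cmax:.2e} > {tail_tol}"
        )
    return inner_coeffs, c


def layered_cylinder_field(
    radii: Sequence[float],
    indices: Sequence[float],
    n_out: float,
    wavelength: float,
    x: np.ndarray,
    z: np.ndarray,
    center: tuple[float, float] = (0.0, 0.0),
    m_max: int | None = None,
) -> dict[str, np.ndarray]:
    """Exact total and scattered field of a plane wave exp(i k_out z)
    hitting a layered cylinder, sampled on the (z, x) grid.

    Returns a dict with complex arrays ``total``, ``scattered`` and
    ``incident`` of shape (len(z), len(x)).
    """
    inner, c = layered_cylinder_coefficients(
        radii, indices, n_out, wavelength, m_max=m_max
    )
    radii = np.asarray(radii, dtype=float)
    k0 = 2.0 * np.pi / wavelength
    ks = np.concatenate([np.asarray(indices, float), [n_out]]) * k0

    X, Z = np.meshgrid(np.asarray(x) - center[0], np.asarray(z) - center[1])
    rho = np.hypot(X, Z)
    phi = np.arctan2(X, Z)  # angle from the propagation (+z) axis
    rho = np.where(rho == 0, 1e-9, rho)

    region = np.searchsorted(radii, rho)  # == len(radii) -> outside
    incident = np.exp(1j * ks[-1] * Z)
    # Outside, sum only the Hankel (scattered) series — its coefficients
    # decay fast, whereas the Bessel re-expansion of the plane wave would
    # need orders up to k*rho to converge far from the cylinder.  Inside,
    # sum the full interior field and subtract the analytic incident.
    scattered = np.zeros(rho.shape, dtype=complex)
    m_top = len(c) - 1
    out = region == len(radii)
    for m in range(m_top + 1):
        eps_m = 1.0 if m == 0 else 2.0
        pref = eps_m * (1j**m) * np.cos(m * phi)
        term = np.zeros(rho.shape, dtype=complex)
        if np.any(out):
            term[out] = c[m] * hankel1(m, ks[-1] * rho[out])
        for j in range(len(radii)):
            sel = region == j
            if not np.any(sel):
                continue
            a_j, b_j = inner[m][j]
            kr = ks[j] * rho[sel]
            val = a_j * jv(m, kr)
            if j > 0:
                val = val + b_j * yv(m, kr)
            term[sel] = val
        scattered += pref * term
    scattered[~out] -= incident[~out]
    return {
        "total": incident + scattered,
        "scattered": scattered,
        "incident": incident,
    }


def single_cylinder_case(
    radius: float = 5.0,
    n_in: float = 1.46,
    n_out: float = 1.36,
    wavelength: float = 0.93,
    coating_thickness: float = 0.0,
    n_coating: float | None = None,
    grid_spacing: float = 0.1,
    domain_half_width: float = 12.0,
) -> FixtureCase:
    """Analytic benchmark: plane wave on a (possibly coated) cylinder.

    The expected scattered/total fields are computed with the series above
    on a square grid centered on the cylinder.  ``radius`` should be at
    least a wavelength for the photonic-jet regime the benchmark targets.
    """
    if radius < wavelength:
        raise ValueError("radius should be >= one wavelength for this benchmark")
    radii = [radius]
    indices = [n_in]
    if coating_thickness > 0:
        radii.append(radius + coating_thickness)
        indices.append(n_coating if n_coating is not None else n_out)
    half = domain_half_width
    x = np.arange(-half, half + grid_spacing / 2, grid_spacing)
    z = x.copy()
    fields = layered_cylinder_field(radii, indices, n_out, wavelength, x, z)
    return FixtureCase(
        name=f"cylinder_r{radius}_n{n_in}_in_{n_out}",
        inputs={
            "radii": radii,
            "indices": indices,
            "n_out": n_out,
            "wavelength": wavelength,
            "x": x,
            "z": z,
        },
        expected=fields,
    )


def lattice_suite(cell: CellModel | None = None, seed: int = 0) -> list[FixtureCase]:
    """The forward-model benchmark grid: beam offsets {0, D/2, D/4} x
    depths {2, 6 layers} x ISF indices {1.36, 1.38, 1.40}.

    Offset 0 aims at the central cell (symmetric incidence), D/2 between
    two cells (symmetric), D/4 half-on half-off (mixed, asymmetric).
    """
    if cell is None:
        cell = CellModel()
    D = cell.outer_diameter
    cases = []
    for offset_name, offset in [("center", 0.0), ("gap", D / 2), ("mixed", D / 4)]:
        for n_layers in (2, 6):
            for n_isf in (1.36, 1.38, 1.40):
                lattice = build_lattice(
                    cell=cell,
                    n_layers=n_layers,
                    cells_per_layer=10,
                    n_ISF=n_isf,
                    packing="square",
                    jitter_fraction=0.0,
                    seed=seed,
                )
                cases.append(
                    FixtureCase(
                        name=f"{offset_name}_L{n_layers}_isf{n_isf:.2f}",
                        inputs={"lattice": lattice, "lateral_offset": offset},
                        expected={
                            "symmetric": offset_name in ("center", "gap"),
                        },
                        seed=seed,
                    )
                )
    return cases


def synth_bscan(
    shape: tuple[int, int] = (300, 500),
    spot_positions: Sequence[int] = (),
    spot_amplitude: float = 100.0,
    noise_sigma: float = 0.0,
    background: float = 100.0,
    bottom_row: int | None = None,
    spot_sigma_px: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic B-scan: constant background, optional Gaussian hot spots
    planted on a bottom-interface row, plus seeded Gaussian noise.

    The construction parameters make the image statistics closed-form:
    with no spots, the relative brightness dispersion is
    ``noise_sigma / background``.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    if spot_positions:
        row = shape[0] - 10 if bottom_row is None else bottom_row
        cols = np.arange(shape[1])
        for pos in spot_positions:
            if not 0 <= pos < shape[1]:
                raise ValueError(f"spot position {pos} outside image width")
            img[row, :] += spot_amplitude * np.exp(
                -((cols - pos) ** 2) / (2.0 * spot_sigma_px**2)
            )
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(img, 0.0, None)
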