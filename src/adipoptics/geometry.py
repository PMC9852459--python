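"""Adipocyte cell models, lattices and rasterized refractive-index fields.

A white-fat adipocyte is modeled as a three-shell dielectric particle: a
large central lipid droplet (n = 1.46, 18 um diameter by default) wrapped
in a thin cytoplasm layer (n = 1.35, 1 um) and a 10 nm cytoplasmic
membrane (n = 1.42), for a total outer diameter of 20.02 um.  Tissue
fragments are close-packed lattices of such cells immersed in interstitial
fluid (ISF, n = 1.36-1.40); a "quasi-regular" variant jitters the cell
positions (and optionally diameters) by ~20% to emulate real tissue
disorder.

Coordinate convention: ``z`` is the propagation axis increasing into the
tissue, the illuminated surface is at ``z = 0``; all lengths are in um;
raster pixel centers sit at ``origin + (i + 0) * spacing`` where ``origin``
is the physical coordinate of pixel (0, 0).

The 2-D solver treats cells as infinite cylinders; 3-D lattices are
supported for en-face (C-scan) rastering, where a constant-y slice of a
sphere lattice yields circles of reduced radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "CellModel",
    "Lattice",
    "IndexField",
    "make_cell",
    "radial_profile",
    "build_lattice",
    "rasterize",
]


@dataclass(frozen=True)
class CellModel:
    """Concentric three-shell refractive-index model of one adipocyte."""

    core_diameter: float = 18.0  # lipid droplet diameter, um
    cytoplasm_thickness: float = 1.0  # um
    membrane_thickness: float = 0.01  # um
    n_core: float = 1.46  # lipid droplet index (n_LD)
    n_cytoplasm: float = 1.35
    n_membrane: float = 1.42
    boundary_softness: float = 0.0  # 0 = hard shell boundaries, um

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise ValueError(
                f"core_diameter must be > 0, got {self.core_diameter}"
            )
        for name in ("cytoplasm_thickness", "membrane_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )
        for name in ("n_core", "n_cytoplasm", "n_membrane"):
            if getattr(self, name) < 1:
                raise ValueError(
                    f"{name} must be >= 1, got {getattr(self, name)}"
                )
        if self.boundary_softness < 0:
            raise ValueError(
                f"boundary_softness must be >= 0, got {self.boundary_softness}"
            )

    @property
    def outer_diameter(self) -> float:
        return (
            self.core_diameter
            + 2.0 * self.cytoplasm_thickness
            + 2.0 * self.membrane_thickness
        )

    @property
    def outer_radius(self) -> float:
        return 0.5 * self.outer_diameter

    def shells(self) -> tuple[np.ndarray, np.ndarray]:
        """Shell boundary radii (ascending) and the index inside each.

        Returns ``(radii, values)`` where ``values[i]`` is the index for
        ``radii[i-1] < r <= radii[i]`` (``values[0]`` inside ``radii[0]``).
        Zero-thickness shells are dropped.
        """
        radii = [0.5 * self.core_diameter]
        values = [self.n_core]
        if self.cytoplasm_thickness > 0:
            radii.append(radii[-1] + self.cytoplasm_thickness)
            values.append(self.n_cytoplasm)
        if self.membrane_thickness > 0:
            radii.append(radii[-1] + self.membrane_thickness)
            values.append(self.n_membrane)
        return np.asarray(radii), np.asarray(values)


def make_cell(
    core_diameter: float = 18.0,
    cytoplasm_thickness: float = 1.0,
    membrane_thickness: float = 0.01,
    n_core: float = 1.46,
    n_cytoplasm: float = 1.35,
    n_membrane: float = 1.42,
    boundary_softness: float = 0.0,
) -> CellModel:
    """Construct and validate a :class:`CellModel` (defaults: the 20.02 um
    three-shell adipocyte)."""
    return CellModel(
        core_diameter=core_diameter,
        cytoplasm_thickness=cytoplasm_thickness,
        membrane_thickness=membrane_thickness,
        n_core=n_core,
        n_cytoplasm=n_cytoplasm,
        n_membrane=n_membrane,
        boundary_softness=boundary_softness,
    )


def _shell_profile(
    r: np.ndarray,
    radii: np.ndarray,
    values: np.ndarray,
    n_embed: float,
    softness: float,
) -> np.ndarray:
    """Radial index profile of a shell stack embedded in ``n_embed``.

    Hard mode (softness 0): piecewise constant.  Soft mode: every shell
    transition is a logistic blend of width ``softness`` centered on the
    boundary (exact midpoint value on the boundary itself).
    """
    r = np.asarray(r, dtype=float)
    levels = np.concatenate([values, [n_embed]])
    if softness > 0:
        n = np.full_like(r, levels[0], dtype=float)
        for rj, lo, hi in zip(radii, levels[:-1], levels[1:]):
            n = n + (hi - lo) * expit(4.0 * (r - rj) / softness)
        return n
    n = np.full_like(r, n_embed, dtype=float)
    for rj, val in zip(radii[::-1], values[::-1]):
        n = np.where(r <= rj, val, n)
    return n


def radial_profile(cell: CellModel, r, n_embed: float = 1.36):
    """Refractive index of ``cell`` at radial distance ``r`` (um).

    ``n_embed`` is the index of the surrounding medium (ISF) returned far
    from the cell.  Accepts scalars or arrays; negative radii raise.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("radial distance r must be >= 0")
    radii, values = cell.shells()
    out = _shell_profile(r_arr, radii, values, n_embed, cell.boundary_softness)
    return float(out) if np.isscalar(r) else out


@dataclass
class Lattice:
    """A (quasi-)regular packing of identical cells in ISF.

    ``cell_centers`` has columns (x, z) in 2-D or (x, y, z) in 3-D;
    ``diameter_scale`` holds the per-cell diameter multiplier (1.0 for a
    regular lattice).
    """

    cell: CellModel
    n_layers: int
    cells_per_layer: int
    n_ISF: float
    packing: Literal["square", "hexagonal"]
    jitter_fraction: float
    seed: int
    cell_centers: np.ndarray
    diameter_scale: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_centers = np.atleast_2d(np.asarray(self.cell_centers, float))
        if self.diameter_scale is None:
            self.diameter_scale = np.ones(len(self.cell_centers))

    @property
    def ndim(self) -> int:
        return self.cell_centers.shape[1]

    @property
    def thickness(self) -> float:
        """Layer-stack thickness along the propagation axis, um."""
        return self.n_layers * self.cell.outer_diameter

    @property
    def lateral_extent(self) -> tuple[float, float]:
        """(min, max) x of cell material for the nominal diameters."""
        r = self.cell.outer_radius
        x = self.cell_centers[:, 0]
        return float(x.min() - r), float(x.max() + r)


def build_lattice(
    cell: CellModel | None = None,
    n_layers: int = 6,
    cells_per_layer: int = 10,
    n_ISF: float = 1.36,
    packing: Literal["square", "hexagonal"] = "square",
    jitter_fraction: float = 0.0,
    seed: int = 0,
    ndim: int = 2,
    jitter_diameters: bool = False,
) -> Lattice:
    """Build a close-packed cell lattice, optionally jittered.

    The regular square packing stacks ``n_layers`` rows of
    ``cells_per_layer`` cells at center spacing equal to the outer cell
    diameter D, the first layer centered at ``z = D/2`` (tissue surface at
    ``z = 0``) and one cell of every row centered on the beam axis
    ``x = 0``.  Hexagonal packing
    offsets alternate rows by D/2 laterally (row spacing stays D, so the
    stack thickness is unchanged).  With ``jitter_fraction`` f > 0, every
    center is displaced per axis by an independent uniform draw from
    [-f*D/2, +f*D/2] and, if ``jitter_diameters``, every diameter is scaled
    by a uniform draw from [1-f, 1+f]; both are reproducible from ``seed``.

    In 3-D (``ndim=3``) each layer is a ``cells_per_layer`` x
    ``cells_per_layer`` square grid in (x, y).
    """
    if cell is None:
        cell = CellModel()
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    if cells_per_layer < 1:
        raise ValueError(f"cells_per_layer must be >= 1, got {cells_per_layer}")
    if not 0.0 <= jitter_fraction < 0.5:
        raise ValueError(
            "jitter_fraction must lie in [0, 0.5): beyond that displaced "
            f"cells could swap order; got {jitter_fraction}"
        )
    if n_ISF < 1:
        raise ValueError(f"n_ISF must be >= 1, got {n_ISF}")
    if ndim not in (2, 3):
        raise ValueError(f"ndim must be 2 or 3, got {ndim}")

    D = cell.outer_diameter
    # a cell center sits exactly on the beam axis x = 0 (for even counts
    # the row extends one cell further to +x)
    lateral = (np.arange(cells_per_layer) - (cells_per_layer - 1) // 2) * D
    z_rows = (np.arange(n_layers) + 0.5) * D

    centers = []
    for i, z in enumerate(z_rows):
        dx = 0.5 * D if (packing == "hexagonal" and i % 2 == 1) else 0.0
        if ndim == 2:
            for x in lateral:
                centers.append((x + dx, z))
        else:
            for x in lateral:
                for y in lateral:
                    centers.append((x + dx, y + dx, z))
    centers = np.asarray(centers, dtype=float)

    scale = np.ones(len(centers))
    if jitter_fraction > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.uniform(
            -jitter_fraction * D / 2.0,
            jitter_fraction * D / 2.0,
            size=centers.shape,
        )
        if jitter_diameters:
            scale = rng.uniform(
                1.0 - jitter_fraction, 1.0 + jitter_fraction, size=len(centers)
            )

    return Lattice(
        cell=cell,
        n_layers=n_layers,
        cells_per_layer=cells_per_layer,
        n_ISF=n_ISF,
        packing=packing,
        jitter_fraction=jitter_fraction,
        seed=seed,
        cell_centers=centers,
        diameter_scale=scale,
    )


@dataclass
class IndexField:
    """Rasterized refractive-index map n(z, x) on a uniform square grid.

    ``n`` is indexed ``[iz, ix]``; ``spacing`` is the pixel pitch in um;
    ``origin = (z0, x0)`` is the physical coordinate of pixel (0, 0).
    """

    n: np.ndarray
    spacing: float
    origin: tuple[float, float]

    @property
    def z(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.n.shape[0]) * self.spacing

    @property
    def x(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.n.shape[1]) * self.spacing

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    def iz(self, z: float) -> int:
        """Nearest row index for physical depth ``z``."""
        return int(round((z - self.origin[0]) / self.spacing))

    def ix(self, x: float) -> int:
        return int(round((x - self.origin[1]) / self.spacing))


def _cells_2d(lattice: Lattice, slice_y: float | None):
    """Per-cell 2-D shell stacks ``(center_xz, radii, values)``.

    For a 3-D lattice, slicing the sphere stack at ``y = slice_y`` turns
    each shell of radius R into a circle of radius sqrt(R^2 - dy^2);
    shells entirely missed by the plane are dropped.
    """
    base_radii, base_values = lattice.cell.shells()
    out = []
    for center, scale in zip(lattice.cell_centers, lattice.diameter_scale):
        radii = base_radii * scale
        if lattice.ndim == 3:
            if slice_y is None:
                raise ValueError("slice_y is required to rasterize a 3-D lattice")
            dy = center[1] - slice_y
            keep = radii > abs(dy)
            if not np.any(keep):
                continue
            radii = np.sqrt(radii[keep] ** 2 - dy * dy)
            values = base_values[keep]
            out.append(((center[0], center[2]), radii, values))
        else:
            out.append(((center[0], center[1]), radii, base_values))
    return out


def rasterize(
    lattice: Lattice,
    grid_spacing: float,
    domain_padding: float | tuple[float, float] = 5.0,
    membrane: Literal["ring", "omit", "exact"] = "ring",
    softness: float | None = None,
    slice_y: float | None = None,
    antialias: int = 1,
) -> IndexField:
    """Rasterize a lattice into an :class:`IndexField`.

    Parameters
    ----------
    grid_spacing : float
        Pixel pitch, um.  Values coarser than ~D/40 under-resolve the
        cytoplasm layer.
    domain_padding : float or (pad_z, pad_x)
        Homogeneous ISF margin added around the cell block, um.
    membrane : {"ring", "omit", "exact"}
        The 10 nm membrane is far below any affordable pixel pitch.  In
        ``"ring"`` mode (default) it is widened to one pixel so the
        membrane index survives rasterization; ``"omit"`` drops it (the
        forward solver's default geometry); ``"exact"`` keeps the true
        10 nm shell (only meaningful for sub-10-nm grids or soft profiles).
    softness : float, optional
        Override the cell's ``boundary_softness`` (um).
    slice_y : float, optional
        For 3-D lattices: y-position of the (x, z) slice plane.
    antialias : int
        Subpixel supersampling factor for hard boundaries: each pixel
        carries the RMS index (permittivity average) over an
        ``antialias x antialias`` subgrid, which suppresses staircase
        artifacts in wave solves.  1 disables it.

    Pixels farther than one cell diameter from every cell carry exactly
    ``n_ISF``.
    """
    if grid_spacing <= 0:
        raise ValueError(f"grid_spacing must be > 0, got {grid_spacing}")
    D = lattice.cell.outer_diameter
    if grid_spacing > D / 40.0:
        import warnings

        warnings.warn(
            f"grid_spacing {grid_spacing:g} um is coarse for a {D:g} um cell "
            "(recommended <= D/40); shells will be poorly resolved",
            stacklevel=2,
        )
    soft = lattice.cell.boundary_softness if softness is None else softness

    pad_z, pad_x = (
        domain_padding
        if isinstance(domain_padding, (tuple, list))
        else (domain_padding, domain_padding)
    )
    cells = _cells_2d(lattice, slice_y)
    if len(lattice.cell_centers):
        x_lo, x_hi = lattice.lateral_extent
    else:
        x_lo = x_hi = 0.0
    z_lo, z_hi = 0.0, lattice.thickness
    x0, x1 = x_lo - pad_x, x_hi + pad_x
    z0, z1 = z_lo - pad_z, z_hi + pad_z
    nx = int(round((x1 - x0) / grid_spacing)) + 1
    nz = int(round((z1 - z0) / grid_spacing)) + 1

    n = np.full((nz, nx), lattice.n_ISF, dtype=np.float64)
    if not cells:
        return IndexField(n=n, spacing=grid_spacing, origin=(z0, x0))

    zc = z0 + np.arange(nz) * grid_spacing
    xc = x0 + np.arange(nx) * grid_spacing
    # closest-boundary distance decides ownership where soft tails overlap
    dmin = np.full((nz, nx), np.inf)

    for (cx, cz), radii, values in cells:
        radii = radii.copy()
        if len(radii) == 3:  # membrane present
            if membrane == "omit":
                radii, values = radii[:2], values[:2]
            elif membrane == "ring":
                radii[2] = radii[1] + max(radii[2] - radii[1], grid_spacing)
        r_out = radii[-1]
        cutoff = r_out + 3.0 * soft + 2.0 * grid_spacing
        i0 = max(0, int((cz - cutoff - z0) / grid_spacing))
        i1 = min(nz, int((cz + cutoff - z0) / grid_spacing) + 2)
        j0 = max(0, int((cx - cutoff - x0) / grid_spacing))
        j1 = min(nx, int((cx + cutoff - x0) / grid_spacing) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        d = np.hypot(
            zc[i0:i1, None] - cz,
            xc[None, j0:j1] - cx,
        )
        owned = (d - r_out < dmin[i0:i1, j0:j1]) & (d <= cutoff)
        if not np.any(owned):
            continue
        vals_arr = np.asarray(values)
        if antialias > 1:
            offs = ((np.arange(antialias) + 0.5) / antialias - 0.5) * grid_spacing
            acc = np.zeros_like(d)
            for oz in offs:
                for ox in offs:
                    dd = np.hypot(
                        zc[i0:i1, None] - cz + oz, xc[None, j0:j1] - cx + ox
                    )
                    acc += _shell_profile(dd, radii, vals_arr, lattice.n_ISF, soft) ** 2
            prof = np.sqrt(acc / antialias**2)
        else:
            prof = _shell_profile(d, radii, vals_arr, lattice.n_ISF, soft)
        patch_n = n[i0:i1, j0:j1]
        patch_d = dmin[i0:i1, j0:j1]
        patch_n[owned] = prof[owned]
        patch_d[owned] = (d - r_out)[owned]

    return IndexField(n=n, spacing=grid_spacing, origin=(z0, x0))
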