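"""Shared fixtures: expensive full-wave solves are session-scoped so the
phenomenology and acceptance tests reuse them."""

from __future__ import annotations

import pytest

from adipoptics.fullwave import lattice_transmittance
from adipoptics.geometry import CellModel

WAVELENGTH = 0.93
N_CORE = 1.46


def solve_lattice(
    n_layers: int,
    n_isf: float,
    lateral_offset: float = 0.0,
    cells_per_layer: int = 10,
    points_per_wavelength: int = 10,
    packing: str = "square",
    softness: float = 0.0,
    tol: float = 1e-4,
):
    """Rasterize-and-solve helper used by several tests (in-line packing
    and hard shells unless stated — the jet-phenomenology geometry)."""
    return lattice_transmittance(
        n_isf,
        n_layers=n_layers,
        cells_per_layer=cells_per_layer,
        packing=packing,
        softness=softness,
        lateral_offset=lateral_offset,
        points_per_wavelength=points_per_wavelength,
        tol=tol,
    )


@pytest.fixture(scope="session")
def six_layer_transmittances():
    """Windowed T of the canonical 6-layer, 10-cell clearing model
    (offset rows, soft shells) at the three ISF indices."""
    out = {}
    for n_isf in (1.36, 1.38, 1.40):
        _, res, _ = lattice_transmittance(n_isf)
        out[n_isf] = res.T
    return out


@pytest.fixture(scope="session")
def two_layer_center_solution():
    """2-layer in-line model, beam centered on an upper-layer cell."""
    sol, res, lattice = solve_lattice(2, 1.36)
    return sol, res, lattice


@pytest.fixture(scope="session")
def two_layer_offset_solution():
    """2-layer in-line model, mixed incidence (offset D/4: half on a cell)."""
    D = CellModel().outer_diameter
    sol, res, lattice = solve_lattice(2, 1.36, lateral_offset=D / 4)
    return sol, res, lattice
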