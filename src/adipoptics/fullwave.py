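"""Full-wave 2-D Helmholtz propagation of a focused beam through a cell field.

Solves the monochromatic scalar Helmholtz equation

    [ d2/dx2 + d2/dz2 + k0^2 n(x,z)^2 ] E = 0

for a Gaussian (or plane-wave) beam incident on a rasterized
refractive-index map, in the scattered-field formulation: the incident
beam is an exact angular-spectrum solution for the homogeneous immersion
medium, and the solver computes the field scattered by the index contrast
(cells, and the absorbing rim standing in for open boundaries).  For TE
polarization (electric field out of the simulation plane) the scalar
equation is Maxwell-exact in 2-D; TM is treated in the same scalar
approximation, adequate for the weak index contrasts of soft tissue.

The scattered field is obtained with a preconditioned convergent Born
series: with background wavenumber kb, contrast V = k^2(r) - kb^2 - i*eps
and the FFT-diagonal Green's function G = 1/(|p|^2 - kb^2 - i*eps), the
iteration

    E <- E + (i/eps) V [ G(V E + S) - E ]

converges monotonically whenever |V| <= eps.  Each iteration costs two
FFTs, so multi-hundred-wavelength domains fit one CPU core in minutes.
Open boundaries are emulated by a rim in which the real index tapers to
the background value while absorption ramps up quadratically (the taper
keeps |V| inside the convergence disc at full absorber strength).

Intensity maps (photonic jets, hot spots) and windowed collimated
transmittance are extracted from the converged total field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Literal

import numpy as np
from scipy import fft as sfft
from scipy.signal import find_peaks

from .geometry import IndexField

__all__ = [
    "BeamSpec",
    "ComplexField",
    "TransmissionResult",
    "HotspotSet",
    "ConvergenceError",
    "incident_field",
    "solve_forward",
    "transmitted_fraction",
    "find_hotspots",
    "lattice_transmittance",
]


class ConvergenceError(RuntimeError):
    """Raised when the Born series fails to reach tolerance.

    Carries the residual history in ``residual_history``.
    """

    def __init__(self, message: str, residual_history: np.ndarray):
        super().__init__(message)
        self.residual_history = np.asarray(residual_history)


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic focused Gaussian beam.

    ``waist_radius`` is the 1/e field half-width w0 at the focus (10 um
    default, i.e. a 20 um undisturbed beam width); ``focus_depth`` places
    the waist along z (0 = at the tissue surface); ``lateral_offset``
    shifts the axis in x (0 hits the central cell of an odd row dead-on,
    D/2 aims between cells).  ``waist_radius=None`` selects a plane wave.
    """

    wavelength: float = 0.93  # um
    waist_radius: float | None = 10.0  # um; None -> plane wave
    focus_depth: float = 0.0  # um
    lateral_offset: float = 0.0  # um
    polarization: Literal["TE", "TM"] = "TE"

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.waist_radius is not None and not (
            self.waist_radius > self.wavelength / 2
        ):
            raise ValueError(
                "waist_radius must exceed wavelength/2 "
                f"(got {self.waist_radius} at wavelength {self.wavelength})"
            )
        if self.polarization not in ("TE", "TM"):
            raise ValueError(f"polarization must be TE or TM, got {self.polarization}")


@dataclass
class ComplexField:
    """Steady-state complex amplitude on an :class:`IndexField` grid."""

    amplitude: np.ndarray  # total field, (nz, nx) complex
    incident: np.ndarray  # incident beam on the same grid
    wavelength: float
    polarization: str
    grid: IndexField
    background_index: float
    residual_history: np.ndarray = dataclass_field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    @property
    def scattered(self) -> np.ndarray:
        return self.amplitude - self.incident


@dataclass(frozen=True)
class TransmissionResult:
    """Windowed collimated transmittance at a plane below the cell stack."""

    T: float
    window_width: float
    z_plane: float
    incident_power: float
    transmitted_power: float


@dataclass(frozen=True)
class HotspotSet:
    """Local intensity maxima along an extraction line."""

    positions: np.ndarray  # lateral coordinates, um, ascending
    intensities: np.ndarray
    prominence_threshold: float

    def __len__(self) -> int:
        return len(self.positions)


def incident_field(
    grid: IndexField,
    beam: BeamSpec,
    n_medium: float,
    dtype=np.complex64,
) -> np.ndarray:
    """Exact homogeneous-medium beam on the grid via the angular spectrum.

    The waist profile exp(-(x - x0)^2 / w0^2) is decomposed into plane
    waves and each component propagated analytically with
    kz = sqrt(k_m^2 - kx^2); evanescent components are discarded.  For
    ``waist_radius=None`` a unit plane wave exp(i k_m z) is returned.
    """
    k_m = 2.0 * np.pi * n_medium / beam.wavelength
    z = grid.z
    x = grid.x
    if beam.waist_radius is None:
        return np.exp(1j * k_m * z)[:, None].astype(dtype) * np.ones(
            (1, len(x)), dtype=dtype
        )
    waist = np.exp(-((x - beam.lateral_offset) ** 2) / beam.waist_radius**2)
    spec = np.fft.fft(waist)
    kx = 2.0 * np.pi * np.fft.fftfreq(len(x), d=grid.spacing)
    kz2 = k_m * k_m - kx * kx
    prop = kz2 > (0.01 * k_m) ** 2  # drop evanescent / grazing components
    kz = np.sqrt(np.where(prop, kz2, 1.0))
    dz = z - beam.focus_depth
    phases = np.exp(1j * np.outer(dz, kz)) * prop[None, :]
    return np.fft.ifft(spec[None, :] * phases, axis=1).astype(dtype)


def _absorber_fraction(nz: int, nx: int, w: int) -> np.ndarray:
    """0 in the interior, rising to 1 at the domain edge over ``w`` pixels."""
    iz = np.arange(nz, dtype=np.float32)
    ix = np.arange(nx, dtype=np.float32)

    def ramp(i, n):
        d = np.minimum(i, n - 1 - i)
        return np.clip(1.0 - d / w, 0.0, 1.0)

    return np.maximum(ramp(iz, nz)[:, None], ramp(ix, nx)[None, :])


def solve_forward(
    index_field: IndexField,
    beam: BeamSpec,
    n_medium: float | None = None,
    absorber_width: float = 24.0,
    nb: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
    dtype=np.complex64,
) -> ComplexField:
    """Solve the steady-state field of ``beam`` through ``index_field``.

    Parameters
    ----------
    index_field : IndexField
        Real 2-D refractive-index map, values >= 1.
    beam : BeamSpec
        Incident beam; must be TE (default) or TM (scalar approximation).
    n_medium : float, optional
        Index of the homogeneous embedding medium the incident beam is
        defined in (default: the corner pixel of the map, i.e. the ISF).
    absorber_width : float
        Width of the absorbing rim added around the domain, um.  Must be
        at least one wavelength; ~24 um keeps residual rim reflections
        below the 0.5% level for tissue-like contrasts.
    nb : float, optional
        Background index of the Born series (default: the contrast-
        minimizing midpoint of the index range).
    tol : float
        Relative update norm at which the series is declared converged.
    max_iter : int
        Iteration budget; exceeding it raises :class:`ConvergenceError`
        with the residual history attached.

    Returns
    -------
    ComplexField
        Total field on the original (uncropped) grid, with the incident
        beam and residual history attached.
    """
    n = np.asarray(index_field.n, dtype=np.float32)
    if n.ndim != 2:
        raise ValueError("index field must be 2-D")
    if n.min() < 1.0:
        raise ValueError(f"refractive index must be >= 1, min is {n.min():.4f}")
    if absorber_width < beam.wavelength:
        raise ValueError(
            f"absorber_width ({absorber_width} um) must be >= one wavelength"
        )
    dx = index_field.spacing
    if n_medium is None:
        n_medium = float(n[0, 0])

    # --- pad with the absorbing rim (and up to FFT-friendly sizes) -------
    w = int(np.ceil(absorber_width / dx))
    nz0, nx0 = n.shape
    nz = sfft.next_fast_len(nz0 + 2 * w)
    nx = sfft.next_fast_len(nx0 + 2 * w)
    pad_z = (w, nz - nz0 - w)
    pad_x = (w, nx - nx0 - w)
    n_pad = np.pad(n, (pad_z, pad_x), mode="edge")

    k0 = 2.0 * np.pi / beam.wavelength
    if nb is None:
        nb = float(np.sqrt(0.5 * (n.min() ** 2 + n.max() ** 2)))
    kb2 = (k0 * nb) ** 2

    k2 = (k0 * n_pad) ** 2
    v_re_max = float(np.max(np.abs(k2 - kb2)))
    eps = 1.05 * max(v_re_max, 1e-3 * kb2)

    # absorbing rim: real index tapers to nb, absorption ramps to 0.9*eps
    frac = _absorber_fraction(nz, nx, max(w - 2, 2))
    k2_eff = k2 + (kb2 - k2) * frac + 1j * (0.9 * eps) * frac * frac
    V = (k2_eff - kb2 - 1j * eps).astype(dtype)
    del k2_eff, frac

    # incident beam on the padded grid (analytic in the uniform medium)
    padded_grid = IndexField(
        n=n_pad,
        spacing=dx,
        origin=(
            index_field.origin[0] - pad_z[0] * dx,
            index_field.origin[1] - pad_x[0] * dx,
        ),
    )
    e_inc = incident_field(padded_grid, beam, n_medium, dtype=dtype)
    k_med2 = (k0 * n_medium) ** 2
    # source from the *physical* contrast only (cells, not the absorbing
    # rim): the incident beam reaches the scatterers unattenuated, while
    # the rim taper/absorption in V still swallows outgoing scattered
    # waves before they can wrap around the periodic FFT domain.
    source = (k2 - k_med2).astype(dtype) * e_inc
    del k2

    # --- Green's function multiplier in Fourier space --------------------
    kzf = (2.0 * np.pi * sfft.fftfreq(nz, d=dx)).astype(np.float32)
    kxf = (2.0 * np.pi * sfft.fftfreq(nx, d=dx)).astype(np.float32)
    p2 = kzf[:, None] ** 2 + kxf[None, :] ** 2
    g_hat = 1.0 / (p2 - kb2 - 1j * eps)
    g_hat = g_hat.astype(dtype)
    del p2

    gamma = (1j / eps) * V
    e_sc = np.zeros((nz, nx), dtype=dtype)
    src_norm = float(np.linalg.norm(source))
    residuals = []
    converged = False
    for it in range(max_iter):
        work = V * e_sc
        work += source
        work = sfft.ifft2(g_hat * sfft.fft2(work, overwrite_x=True), overwrite_x=True)
        work -= e_sc
        work *= gamma
        e_sc += work
        if it % 5 == 4 or it < 5:
            res = float(np.linalg.norm(work)) / max(
                float(np.linalg.norm(e_sc)), 1e-30
            )
            residuals.append(res)
            if res < tol:
                converged = True
                break
    if not converged:
        raise ConvergenceError(
            f"Born series did not reach tol={tol} in {max_iter} iterations "
            f"(last residual {residuals[-1]:.3e})",
            np.asarray(residuals),
        )

    sl_z = slice(pad_z[0], pad_z[0] + nz0)
    sl_x = slice(pad_x[0], pad_x[0] + nx0)
    e_inc_crop = e_inc[sl_z, sl_x]
    total = e_inc_crop + e_sc[sl_z, sl_x]
    return ComplexField(
        amplitude=total,
        incident=e_inc_crop,
        wavelength=beam.wavelength,
        polarization=beam.polarization,
        grid=index_field,
        background_index=nb,
        residual_history=np.asarray(residuals),
    )


def _flux_profile(e: np.ndarray, iz: int, dx: float) -> np.ndarray:
    """Longitudinal Poynting-vector component Im(E* dE/dz) along row iz."""
    dez = (e[iz + 1, :] - e[iz - 1, :]) / (2.0 * dx)
    return np.imag(np.conj(e[iz, :]).astype(np.complex128) * dez)


def transmitted_fraction(
    field: ComplexField,
    z_plane: float,
    window_width: float = 20.0,
    window_center: float = 0.0,
    method: Literal["flux", "intensity"] = "flux",
    normalization: Literal["total", "window"] = "total",
) -> TransmissionResult:
    """Collimated transmittance through a lateral window at ``z_plane``.

    The 20 um default window equals the width of the undisturbed
    incident beam (and roughly one cell cross-section).  Two measurement
    conventions are provided:

    * ``method="flux"`` (default): power flux from the longitudinal
      Poynting component Im(E* dE/dz).  With ``normalization="total"``
      (the whole incident beam power) T is bounded by 1 in lossless
      media.
    * ``method="intensity"``: integral of |E|^2 across the window — the
      photometric reading of a detector behind a slit.  Combined with
      ``normalization="window"`` (incident |E|^2 integrated over the
      same window at the entry plane) this is the convention of the
      optical-clearing transmittance table; focusing can push it above 1.
    """
    grid = field.grid
    dx = grid.spacing
    iz = grid.iz(z_plane)
    if iz < 1 or iz >= grid.shape[0] - 1:
        raise ValueError(f"z_plane {z_plane} um is outside the domain")
    x = grid.x
    lo = window_center - window_width / 2.0
    hi = window_center + window_width / 2.0
    if lo < x[0] or hi > x[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] um extends outside the domain "
            f"[{x[0]:.1f}, {x[-1]:.1f}]"
        )
    in_window = (x >= lo) & (x <= hi)
    # incident reference at the beam's narrowest plane inside the domain
    iz_inc = int(np.clip(grid.iz(0.0), 1, grid.shape[0] - 2))

    if method == "flux":
        out_profile = _flux_profile(field.amplitude, iz, dx)
        in_profile = _flux_profile(field.incident, iz_inc, dx)
    elif method == "intensity":
        out_profile = np.abs(field.amplitude[iz, :].astype(np.complex128)) ** 2
        in_profile = np.abs(field.incident[iz_inc, :].astype(np.complex128)) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")

    transmitted = float(np.sum(out_profile[in_window]) * dx)
    if normalization == "total":
        incident = float(np.sum(in_profile) * dx)
    elif normalization == "window":
        incident = float(np.sum(in_profile[in_window]) * dx)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    return TransmissionResult(
        T=transmitted / incident,
        window_width=window_width,
        z_plane=z_plane,
        incident_power=incident,
        transmitted_power=transmitted,
    )


def find_hotspots(
    field: ComplexField,
    extraction_line_z: float,
    min_prominence: float = 0.1,
) -> HotspotSet:
    """Hot spots (local intensity maxima) along a horizontal line.

    ``min_prominence`` is relative to the line's peak intensity; an empty
    set is a valid result.
    """
    grid = field.grid
    iz = grid.iz(extraction_line_z)
    if iz < 0 or iz >= grid.shape[0]:
        raise ValueError(f"extraction line z={extraction_line_z} outside domain")
    profile = np.abs(field.amplitude[iz, :].astype(np.complex128)) ** 2
    threshold = min_prominence * float(profile.max())
    peaks, props = find_peaks(profile, prominence=threshold)
    order = np.argsort(grid.x[peaks])
    return HotspotSet(
        positions=grid.x[peaks][order],
        intensities=profile[peaks][order],
        prominence_threshold=threshold,
    )


def lattice_transmittance(
    n_isf: float,
    n_layers: int = 6,
    cells_per_layer: int = 10,
    packing: str = "hexagonal",
    softness: float = 0.5,
    lateral_offset: float = 0.0,
    points_per_wavelength: int = 10,
    window_width: float = 20.0,
    beam: BeamSpec | None = None,
    tol: float = 1e-4,
):
    """Canonical tissue-clearing run: solve a cell lattice and measure T.

    Builds the close-packed adipocyte lattice (offset rows by default —
    in-line stacking turns the cell columns into a lens waveguide and
    overestimates T dramatically), rasterizes it with soft cell
    boundaries at a grid of lambda/(ppw * n_core), solves the beam, and
    reads the transmitted intensity through the 20 um window directly
    below the last cell layer, normalized to the incident beam's
    intensity through the same window (the photometric convention of the
    optical-clearing transmittance table).

    Returns ``(solution, transmission, lattice)``.
    """
    from .geometry import build_lattice, rasterize

    lattice = build_lattice(
        n_layers=n_layers,
        cells_per_layer=cells_per_layer,
        n_ISF=n_isf,
        packing=packing,
    )
    if beam is None:
        beam = BeamSpec(lateral_offset=lateral_offset)
    dx = beam.wavelength / (points_per_wavelength * lattice.cell.n_core)
    field = rasterize(
        lattice,
        dx,
        domain_padding=(4.0, 8.0),
        membrane="omit",
        softness=softness,
        antialias=1 if softness > 0 else 2,
    )
    solution = solve_forward(field, beam, tol=tol)
    result = transmitted_fraction(
        solution,
        z_plane=lattice.thickness + 0.3,
        window_width=window_width,
        window_center=beam.lateral_offset,
        method="intensity",
        normalization="window",
    )
    return solution, result, lattice
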