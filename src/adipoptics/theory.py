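"""Analytic collimated transmittance of a close-packed adipocyte layer.

The collimated (ballistic) transmittance of a non-absorbing layer of
scatterers follows the Bouguer–Beer–Lambert law

    T = I(l) / I0 = exp(-mu_s * l),

with the scattering coefficient of large, weakly contrasting Mie particles
estimated as

    mu_s = a^2 * rho_s * (m - 1)^2,       m = n_LD / n_ISF,

where ``m`` is the refractive-index ratio between the adipocyte lipid
droplet (n_LD) and the interstitial fluid that surrounds the cells (n_ISF).
Index matching (m -> 1) switches scattering off entirely — the mechanism of
optical clearing by heating-driven lipolysis or immersion agents.

Convention for ``a`` and ``rho_s``
----------------------------------
The product ``a^2 * rho_s`` has units of inverse length and is the only
combination that enters the law.  For a monolayer-stacked close packing of
cells of outer diameter D, one cell occupies a D x D column cross-section,
so with a = D and rho_s = 1 / (D^2 * 1 um) the product is exactly
1 um^-1.  This close-packing convention is the package default; any other
reading can be supplied through the explicit ``a2rho`` argument of
:func:`transmittance_from_indices` and :func:`relative_index_from_T`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CLOSE_PACKING_A2RHO",
    "TheoryResult",
    "scattering_coefficient",
    "transmittance",
    "transmittance_from_indices",
    "relative_index_from_T",
]

#: a^2 * rho_s for a close-packed monolayer stack of cells, um^-1.
CLOSE_PACKING_A2RHO = 1.0


@dataclass(frozen=True)
class TheoryResult:
    """Scattering coefficient, transmittance and (optionally) the inverted
    relative refractive index for one layer configuration."""

    mu_s: float  # scattering coefficient, um^-1
    T: float  # transmittance fraction in (0, 1]
    m_reconstructed: float | None = None  # n_LD / n_ISF from inversion

    def __post_init__(self) -> None:
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not 0.0 < self.T <= 1.0 + 1e-12:
            raise ValueError(f"T must lie in (0, 1], got {self.T}")


def scattering_coefficient(a: float, rho_s: float, m: float) -> float:
    """Mie-estimate scattering coefficient ``mu_s = a^2 rho_s (m-1)^2``.

    Parameters
    ----------
    a : float
        Particle size entering the estimate, um (outer cell diameter under
        the close-packing convention).
    rho_s : float
        Particle number density, um^-3.
    m : float
        Relative refractive index n_LD / n_ISF.

    Returns
    -------
    float
        Scattering coefficient in um^-1.  Zero when the indices match.
    """
    if a <= 0:
        raise ValueError(f"particle size a must be > 0, got {a}")
    if rho_s <= 0:
        raise ValueError(f"particle density rho_s must be > 0, got {rho_s}")
    if m <= 0:
        raise ValueError(f"relative index m must be > 0, got {m}")
    return a * a * rho_s * (m - 1.0) ** 2


def transmittance(mu_s: float, l: float) -> float:
    """Bouguer–Beer–Lambert transmittance ``T = exp(-mu_s l)``.

    ``mu_s`` in um^-1 and the layer thickness ``l`` in um.
    """
    if mu_s < 0:
        raise ValueError(f"mu_s must be >= 0, got {mu_s}")
    if l < 0:
        raise ValueError(f"thickness l must be >= 0, got {l}")
    return math.exp(-mu_s * l)


def transmittance_from_indices(
    n_LD: float,
    n_ISF: float,
    l: float,
    a2rho: float = CLOSE_PACKING_A2RHO,
) -> TheoryResult:
    """Forward model: indices and thickness to (mu_s, T).

    Parameters
    ----------
    n_LD, n_ISF : float
        Refractive indices of the lipid droplet and the interstitial fluid.
    l : float
        Layer thickness, um.
    a2rho : float
        The combination a^2 * rho_s, um^-1 (default: close packing, 1.0).
    """
    if n_LD < 1 or n_ISF < 1:
        raise ValueError("refractive indices must be >= 1")
    if a2rho <= 0:
        raise ValueError(f"a2rho must be > 0, got {a2rho}")
    m = n_LD / n_ISF
    mu_s = a2rho * (m - 1.0) ** 2
    return TheoryResult(mu_s=mu_s, T=transmittance(mu_s, l))


def relative_index_from_T(
    T: float,
    l: float,
    a2rho: float = CLOSE_PACKING_A2RHO,
) -> float:
    """Invert the transmittance law for the relative index m = n_LD/n_ISF.

    ``m = 1 + sqrt(-ln T / (a2rho * l))``.  Round-trips exactly with
    :func:`transmittance_from_indices` for m > 1.

    Raises
    ------
    ValueError
        If ``T`` is outside (0, 1] or ``l``/``a2rho`` are non-positive.
    """
    if not 0.0 < T <= 1.0:
        raise ValueError(f"T must lie in (0, 1], got {T}")
    if l <= 0 or a2rho <= 0:
        raise ValueError("l and a2rho must be > 0")
    return 1.0 + math.sqrt(-math.log(T) / (a2rho * l))
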