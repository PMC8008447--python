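"""Geometric and hydrodynamic protein-corona estimates.

Given the radii of the bare nanoparticle and of the protein-coated complex
(from DLS or SANS), the number of proteins in the corona is estimated from the
spherical-shell volume available to them:

    N = (4/3) pi (R_complex^3 - R_np^3) / V_protein

The maximum side-on monolayer is the sphere surface divided by the protein's
flat-face footprint. Hydrodynamic radii come from Stokes-Einstein
(R_H = k_B T / 6 pi eta D) and zeta potentials from the Smoluchowski limit
(zeta = eta mu / epsilon).

Lengths are in Å unless a function says otherwise; helpers for nm/Å/m
conversions are provided (and round-trip exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as K_B

__all__ = [
    "CoronaGeometry",
    "ellipsoid_volume",
    "triangular_prism_volume",
    "bound_protein_count",
    "monolayer_capacity",
    "stokes_einstein_radius",
    "stokes_einstein_diffusion",
    "smoluchowski_zeta",
    "nm_to_angstrom",
    "angstrom_to_nm",
    "HSA_OBLATE_VOLUME",
    "HSA_PRISM_VOLUME",
    "HSA_TRIANGLE_FOOTPRINT",
]


def nm_to_angstrom(x: float) -> float:
    return x * 10.0


def angstrom_to_nm(x: float) -> float:
    return x / 10.0


def ellipsoid_volume(a_minor: float, b_major: float, shape: str = "oblate") -> float:
    """Ellipsoid-of-revolution volume (ų): oblate (4/3)pi a b^2, prolate
    (4/3)pi a^2 b."""
    if a_minor <= 0 or b_major <= 0:
        raise ValueError("axes must be positive")
    if shape == "oblate":
        return 4.0 / 3.0 * np.pi * a_minor * b_major**2
    if shape == "prolate":
        return 4.0 / 3.0 * np.pi * a_minor**2 * b_major
    raise ValueError("shape must be 'oblate' or 'prolate'")


def triangular_prism_volume(edge: float, thickness: float) -> float:
    """Equilateral-triangular prism volume (ų): (sqrt(3)/4) edge^2 thickness."""
    return np.sqrt(3.0) / 4.0 * edge**2 * thickness


def equilateral_triangle_area(edge: float) -> float:
    """Flat-face footprint (Ų) of a triangular protein bound side-on."""
    return np.sqrt(3.0) / 4.0 * edge**2


# Serum-albumin presets: an oblate ellipsoid with the SANS semi-axes
# (22 Å x 72 Å), and a triangular prism with 80 Å edges and 35 Å thickness
# (the protein's crystallographic heart shape approximated as a flat triangle).
HSA_OBLATE_VOLUME = ellipsoid_volume(22.0, 72.0, "oblate")  # ~4.78e5 ų
HSA_PRISM_VOLUME = triangular_prism_volume(80.0, 35.0)  # ~9.7e4 ų
HSA_TRIANGLE_FOOTPRINT = equilateral_triangle_area(80.0)  # ~2771 Ų

PROTEIN_VOLUME_PRESETS = {
    "hsa-oblate": HSA_OBLATE_VOLUME,
    "hsa-prism": HSA_PRISM_VOLUME,
}


@dataclass
class CoronaGeometry:
    """Radii and protein volume entering the shell-volume estimate (Å, ų)."""

    R_np: float
    R_complex: float
    V_protein: float
    footprint_area: float | None = None

    def __post_init__(self) -> None:
        if self.R_np <= 0:
            raise ValueError("R_np must be positive")
        if self.R_complex < self.R_np:
            raise ValueError("R_complex must be >= R_np")
        if self.V_protein <= 0:
            raise ValueError("V_protein must be positive")


def bound_protein_count(geometry: CoronaGeometry) -> tuple[float, int]:
    """Shell-volume estimate of the number of bound proteins.

    Returns (real-valued N, nearest integer). R_complex = R_np yields N = 0.
    N is monotone increasing in R_complex and inversely proportional to
    V_protein.
    """
    shell = 4.0 / 3.0 * np.pi * (geometry.R_complex**3 - geometry.R_np**3)
    n_real = shell / geometry.V_protein
    return float(n_real), int(round(n_real))


def monolayer_capacity(R_np: float, footprint_area: float) -> float:
    """Maximum side-on monolayer count: 4 pi R_np^2 / footprint."""
    if R_np <= 0 or footprint_area <= 0:
        raise ValueError("inputs must be positive")
    return 4.0 * np.pi * R_np**2 / footprint_area


def stokes_einstein_radius(D: float, T: float = 298.15, viscosity: float = 8.9e-4) -> float:
    """Hydrodynamic radius (m) from a translational diffusion coefficient.

    R_H = k_B T / (6 pi eta D); D in m²/s, T in K, eta in Pa·s.
    """
    if D <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("inputs must be positive")
    return K_B * T / (6.0 * np.pi * viscosity * D)


def stokes_einstein_diffusion(R_H: float, T: float = 298.15, viscosity: float = 8.9e-4) -> float:
    """Inverse of :func:`stokes_einstein_radius` (exact round trip)."""
    if R_H <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("inputs must be positive")
    return K_B * T / (6.0 * np.pi * viscosity * R_H)


def smoluchowski_zeta(
    mobility: float, viscosity: float = 8.9e-4, permittivity: float = 6.95e-10
) -> float:
    """Zeta potential (V) in the Smoluchowski limit: zeta = eta mu / epsilon.

    mobility in m² V^-1 s^-1, viscosity in Pa·s, permittivity in F/m (the
    default is water's absolute permittivity at 25 °C). The sign of zeta
    follows the sign of the mobility.
    """
    if viscosity <= 0 or permittivity <= 0:
        raise ValueError("viscosity and permittivity must be positive")
    return viscosity * mobility / permittivity
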