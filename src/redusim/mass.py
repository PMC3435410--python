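"""Prostate mass dynamics driven by gene occupancy.

The androgen-sensitive cellular compartment VPC_1 grows with occupancy of
the proliferation gene and dies at a rate modulated by loss of
anti-apoptotic occupancy; the ductal lumen compartment VPL_1 fills with
secreted fluid under the fluid-production gene and clears first-order.
Two basal, androgen-insensitive compartments (VPC_2, VPL_2) are constant.
The death and lumen-clearance rate constants are forced so that both
derivatives vanish exactly at the intact anchors.
"""

from __future__ import annotations

from .parameters import GeneRegParams, MassParams

__all__ = ["mass_derivatives", "force_death_constants", "total_prostate_mass"]


def force_death_constants(mass: MassParams, gene: GeneRegParams) -> tuple[float, float]:
    """Return ``(k_cd1, k_lum)``, hr^-1, forced by the intact steady state.

    ``k_cd1 = k_cp1*DNAo_cp0 / ((1 - DNAo_cd0)*VPC_1b)`` and
    ``k_lum = k_sec*DNAo_sec0 / VPL_1b`` guarantee zero mass derivatives at
    the occupancy anchors.
    """
    if gene.DNAo_cd0 >= 1.0:
        raise ValueError("DNAo_cd0 must be < 1 (death-rate forcing divides by 1 - anchor)")
    k_cd1 = mass.k_cp1 * gene.DNAo_cp0 / ((1.0 - gene.DNAo_cd0) * mass.VPC_1b)
    k_lum = mass.k_sec * gene.DNAo_sec0 / mass.VPL_1b
    return k_cd1, k_lum


def mass_derivatives(
    VPC_1: float,
    VPL_1: float,
    DNAo_cp: float,
    DNAo_cd: float,
    DNAo_sec: float,
    mass: MassParams,
    k_cd1: float,
    k_lum: float,
) -> tuple[float, float]:
    """Derivatives of the androgen-sensitive cellular and lumen masses, mg/hr."""
    dVPC_1 = mass.k_cp1 * DNAo_cp - k_cd1 * (1.0 - DNAo_cd) * VPC_1
    dVPL_1 = mass.k_sec * DNAo_sec - k_lum * VPL_1
    return dVPC_1, dVPL_1


def total_prostate_mass(VPC_1: float, VPL_1: float, mass: MassParams) -> float:
    """Total prostate mass, mg: androgen-sensitive plus basal compartments."""
    return VPC_1 + mass.VPC_2 + VPL_1 + mass.VPL_2
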