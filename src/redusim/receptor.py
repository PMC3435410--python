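"""Androgen receptor binding, dimerization and gene occupancy.

Free T and DHT bind AR to form the ART and ARD monomer complexes, which
are dynamic states.  Homo- and heterodimer concentrations (TT, TD, DD)
and the fractional occupancies of the four regulated gene programs (cell
proliferation, anti-apoptosis, fluid production, 5aR2 production) are
algebraic quasi-equilibrium quantities computed from the monomer levels:
dimerization and DNA binding equilibrate much faster than receptor and
androgen turnover, and available dimers exceed DNA sites roughly 40-fold,
so site depletion is negligible and occupancy is a saturating function of
a potency-weighted dimer pool.  TT dimers are weaker transactivators than
DD; their potency is divided by ``k_DNAoffTT`` (1.6), with the heterodimer
weighted by the geometric mean.
"""

from __future__ import annotations

from .parameters import GeneRegParams

__all__ = [
    "GENES",
    "receptor_derivatives",
    "dimer_concentrations",
    "dimer_potency",
    "gene_occupancy",
]

#: Identifiers of the four regulated gene programs.
GENES = ("cp", "cd", "sec", "5aR2")


def receptor_derivatives(
    AR: float,
    ART: float,
    ARD: float,
    CT_pf: float,
    CD_pf: float,
    gene: GeneRegParams,
    kAR_syn: float,
) -> tuple[float, float, float, float, float]:
    """Derivatives of AR, ART, ARD (nM/hr) plus the net ligand binding fluxes.

    Returns ``(dAR, dART, dARD, T_net_binding, DHT_net_binding)``.  The net
    binding fluxes (nM/hr) are what the free prostatic androgen balances
    lose to the receptor; ligand carried by complexes that are degraded is
    returned to the free pool by the caller (mass conservation), so the
    exported fluxes here are the association/dissociation terms only.
    """
    bT = gene.konT * CT_pf * AR - gene.koffT * ART
    bD = gene.konD * CD_pf * AR - gene.koffD * ARD
    dAR = kAR_syn - gene.kAR_deg * AR - bT - bD
    dART = bT - gene.kAR_deg * ART
    dARD = bD - gene.kAR_deg * ARD
    return dAR, dART, dARD, bT, bD


def dimer_concentrations(ART: float, ARD: float, gene: GeneRegParams) -> tuple[float, float, float]:
    """Quasi-equilibrium dimer concentrations (TT, TD, DD), nM.

    A single association constant with the statistical factor 2 for the
    heterodimer: ``TT = kdim*ART^2``, ``TD = 2*kdim*ART*ARD``,
    ``DD = kdim*ARD^2``.
    """
    TT = gene.kdim * ART * ART
    TD = 2.0 * gene.kdim * ART * ARD
    DD = gene.kdim * ARD * ARD
    return TT, TD, DD


def dimer_potency(TT: float, TD: float, DD: float, gene: GeneRegParams) -> float:
    """Potency-weighted dimer pool driving gene occupancy, nM-equivalents."""
    return DD + gene.w_TD * TD + TT / gene.k_DNAoffTT


def gene_occupancy(
    TT: float,
    TD: float,
    DD: float,
    gene_id: str,
    gene: GeneRegParams,
    K_occ: dict[str, float],
) -> float:
    """Fractional occupancy of one gene program's response elements.

    ``S = potency / K_occ[gene_id]``; occupancy ``= S / (1 + S)``.  The
    half-saturation constants ``K_occ`` are forced from the intact anchors.
    """
    if gene_id not in K_occ:
        raise KeyError(f"unknown gene id {gene_id!r}; expected one of {GENES}")
    S = dimer_potency(TT, TD, DD, gene) / K_occ[gene_id]
    return S / (1.0 + S)
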