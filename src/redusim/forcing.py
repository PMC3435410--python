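"""Intact steady-state construction by algebraic forcing.

The base model's unprinted constants are not free-floating: the intact
animal is, by definition, at steady state, and the printed anchors (free
5aR2 = 19 nM, 5aR2:T = 1 nM, occupancies 0.95, total mass 457 mg, blood
T and DHT levels) pin one forced constant per balance equation.  This
module solves those forcing relations in closed form (one scalar root
find for the liver) and assembles the exact intact steady-state vector.

Forced here, in order:

1. free prostatic T from the enzyme partition: ``CT_pf0 = Km*ET0/E0``;
2. liver free T (root of the flow/metabolism/elimination balance) and DHT;
3. prostate blood flow ``Qp0`` so the prostatic T balance closes, which
   simultaneously fixes free prostatic DHT ``CD_pf0``;
4. testicular production ``kT_prod`` so the blood T balance closes;
5. blood-side DHT clearance ``CL_blD`` so the blood DHT balance closes;
6. LH production so ``dLH = 0`` at the normalized intact level;
7. AR synthesis and the monomer complexes from binding quasi-steady state;
8. per-gene half-saturation constants ``K_occ`` from the occupancy anchors;
9. prostate death/lumen-clearance constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .liver import inhibited_mm_rate
from .mass import force_death_constants
from .parameters import ModelParameters, validate_parameters
from .receptor import dimer_concentrations, dimer_potency
from .state import S, new_state

__all__ = ["ForcedConstants", "force_steady_state", "MG_TO_L"]

#: 1 mg of prostate tissue occupies 1 uL = 1e-6 L.
MG_TO_L = 1e-6


@dataclass
class ForcedConstants:
    """Constants solved from the intact anchors (see module docstring)."""

    CT_pf0: float
    CD_pf0: float
    CT_l0: float
    CD_l0: float
    V_p0: float          # mg
    Qp0: float           # L/hr
    PS_pD0: float        # L/hr, diffusion-limited DHT blood<->prostate transfer
    kT_prod: float       # nmol/hr per LH unit
    CL_blD: float        # L/hr
    kLH_prod: float      # units/hr
    AR0: float           # nM (free)
    ART0: float
    ARD0: float
    kAR_syn: float       # nM/hr
    K_occ: dict[str, float] = field(default_factory=dict)
    k_cd1: float = 0.0   # hr^-1
    k_lum: float = 0.0   # hr^-1

    def copy(self) -> "ForcedConstants":
        return replace(self, K_occ=dict(self.K_occ))


def _liver_free_T(params: ModelParameters) -> float:
    lv = params.liver
    CT_bl0 = params.axis.CT_bl0

    def f(C: float) -> float:
        return lv.Q_l * (CT_bl0 - C) - inhibited_mm_rate(C, 0.0, lv) - lv.k_lT * lv.V_l * C

    return brentq(f, 0.0, CT_bl0, xtol=1e-14, rtol=1e-14)


def force_steady_state(params: ModelParameters) -> tuple[ForcedConstants, np.ndarray]:
    """Solve all forcing relations; return the constants and the intact state."""
    validate_parameters(params)
    en, gn, ms, ax, lv = params.enzyme, params.gene, params.mass, params.axis, params.liver

    # 1. enzyme partition pins free prostatic T
    CT_pf0 = en.Km * en.ET0 / en.E_free0

    # 2. liver
    CT_l0 = _liver_free_T(params)
    mm0 = inhibited_mm_rate(CT_l0, 0.0, lv)
    CD_l0 = (lv.Q_l * ax.CD_bl0 + mm0) / (lv.Q_l + lv.k_lD * lv.V_l)

    # 3. prostate transport: T uptake is flow-limited (the prostate extracts
    # nearly all incoming T at the intact state), DHT efflux is
    # diffusion-limited so free tissue DHT can sit far above blood levels
    V_p0 = ms.V_p_total0
    R_p = en.kcat * en.ET0 * V_p0 * MG_TO_L          # nmol/hr of T in, DHT out
    Qp0 = R_p / (ax.CT_bl0 - CT_pf0)
    CD_pf0 = ax.CD_pf0
    PS_pD0 = R_p / (CD_pf0 - ax.CD_bl0)

    # 4.-5. testicular production and blood DHT clearance
    kT_prod = (lv.Q_l * (ax.CT_bl0 - CT_l0) + Qp0 * (ax.CT_bl0 - CT_pf0)) / ax.LH0
    CL_blD = (lv.Q_l * (CD_l0 - ax.CD_bl0) + PS_pD0 * (CD_pf0 - ax.CD_bl0)) / ax.CD_bl0

    # 6. LH production
    u0 = (ax.CT_bl0 + ax.CD_bl0) / ax.K_inh
    kLH_prod = ax.kLH_deg * ax.LH0 * (1.0 + u0 ** ax.n_hill)

    # 7. AR turnover and monomer complexes
    AR0 = gn.AR_free0
    ART0 = gn.konT * CT_pf0 * AR0 / (gn.koffT + gn.kAR_deg)
    ARD0 = gn.konD * CD_pf0 * AR0 / (gn.koffD + gn.kAR_deg)
    kAR_syn = gn.kAR_deg * (AR0 + ART0 + ARD0)

    # 8. occupancy half-saturation constants
    TT0, TD0, DD0 = dimer_concentrations(ART0, ARD0, gn)
    P0 = dimer_potency(TT0, TD0, DD0, gn)
    anchors = {
        "cp": gn.DNAo_cp0,
        "cd": gn.DNAo_cd0,
        "sec": gn.DNAo_sec0,
        "5aR2": gn.DNAo_5aR20,
    }
    K_occ = {g: P0 * (1.0 - a) / a for g, a in anchors.items()}

    # 9. mass balance forcings
    k_cd1, k_lum = force_death_constants(ms, gn)

    forced = ForcedConstants(
        CT_pf0=CT_pf0, CD_pf0=CD_pf0, CT_l0=CT_l0, CD_l0=CD_l0,
        V_p0=V_p0, Qp0=Qp0, PS_pD0=PS_pD0,
        kT_prod=kT_prod, CL_blD=CL_blD, kLH_prod=kLH_prod,
        AR0=AR0, ART0=ART0, ARD0=ARD0, kAR_syn=kAR_syn,
        K_occ=K_occ, k_cd1=k_cd1, k_lum=k_lum,
    )

    x0 = new_state()
    V_p0L = V_p0 * MG_TO_L
    x0[S.AT_L] = CT_l0 * lv.V_l * lv.PT_l
    x0[S.AD_L] = CD_l0 * lv.V_l * lv.PD_l
    x0[S.AT_BL] = ax.CT_bl0 * ax.V_bl
    x0[S.AD_BL] = ax.CD_bl0 * ax.V_bl
    x0[S.AT_BD] = ax.CT_bl0 * ax.V_bd
    x0[S.AD_BD] = ax.CD_bl0 * ax.V_bd
    x0[S.LH] = ax.LH0
    x0[S.AT_P] = CT_pf0 * ax.PT_p * V_p0L
    x0[S.AD_P] = CD_pf0 * ax.PD_p * V_p0L
    x0[S.E] = en.E_free0
    x0[S.ET] = en.ET0
    x0[S.AR] = AR0
    x0[S.ART] = ART0
    x0[S.ARD] = ARD0
    x0[S.VPC_1] = ms.VPC_1b
    x0[S.VPL_1] = ms.VPL_1b
    return forced, x0
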