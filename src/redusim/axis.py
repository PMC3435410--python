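"""Whole-body androgen PBPK and the testicular-pituitary LH feedback loop.

Blood exchanges T and DHT flow-limited with the liver, the lumped body
compartment (brain and all unmodeled tissues) and the prostate.  Blood
androgens inhibit LH production through a Hill function; LH drives
testicular T production, closing a negative feedback loop.  Castration
sets testicular production to zero.  A nonspecific blood-side DHT
clearance (forced from the intact steady state) folds the base model's
extra-hepatic elimination routes into one term.
"""

from __future__ import annotations

from .parameters import AxisParams

__all__ = ["lh_production", "axis_derivatives"]


def lh_production(CT_bl: float, CD_bl: float, axis: AxisParams, kLH_prod: float) -> float:
    """LH production rate (normalized units/hr) under androgen feedback."""
    u = (CT_bl + CD_bl) / axis.K_inh
    return kLH_prod / (1.0 + u ** axis.n_hill)


def axis_derivatives(
    AT_bl: float,
    AD_bl: float,
    AT_bd: float,
    AD_bd: float,
    LH: float,
    CT_l: float,
    CD_l: float,
    CT_pf: float,
    CD_pf: float,
    Q_p: float,
    PS_pD: float,
    axis: AxisParams,
    Q_l: float,
    kLH_prod: float,
    kT_prod: float,
    CL_blD: float,
    testes_on: bool = True,
) -> tuple[float, float, float, float, float]:
    """Blood, body and LH derivatives.

    Returns ``(dAT_bl, dAD_bl, dAT_bd, dAD_bd, dLH)``; amounts in nmol/hr,
    LH in normalized units/hr.  ``testes_on=False`` implements castration.
    Prostatic T exchanges flow-limited (coefficient ``Q_p``); prostatic DHT
    exchanges through the diffusion-limited coefficient ``PS_pD``.
    """
    CT_bl = AT_bl / axis.V_bl
    CD_bl = AD_bl / axis.V_bl
    CT_bd = AT_bd / axis.V_bd
    CD_bd = AD_bd / axis.V_bd

    prod_T = kT_prod * LH if testes_on else 0.0

    dAT_bl = (
        Q_l * (CT_l - CT_bl)
        + axis.Q_bd * (CT_bd - CT_bl)
        + Q_p * (CT_pf - CT_bl)
        + prod_T
    )
    dAD_bl = (
        Q_l * (CD_l - CD_bl)
        + axis.Q_bd * (CD_bd - CD_bl)
        + PS_pD * (CD_pf - CD_bl)
        - CL_blD * CD_bl
    )
    dAT_bd = axis.Q_bd * (CT_bl - CT_bd)
    dAD_bd = axis.Q_bd * (CD_bl - CD_bd)
    dLH = lh_production(CT_bl, CD_bl, axis, kLH_prod) - axis.kLH_deg * LH
    return dAT_bl, dAD_bl, dAT_bd, dAD_bd, dLH
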