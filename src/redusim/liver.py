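"""Hepatic testosterone metabolism under competitive 5aR1 inhibition.

The liver converts T to DHT through 5aR1 with Michaelis-Menten kinetics;
finasteride inhibits 5aR1 competitively and reversibly, which multiplies
the apparent Km by ``(1 + F_free/Ki_5aR1)``.  5aR1 activity is assumed
constant: it is not androgen regulated, so the same Vmax applies to
intact, castrated and treated scenarios.  Nonspecific hepatic elimination
of T and DHT is first-order in the free liver concentration, applied as
``k * V_l * C`` (the printed rate constants act as clearance coefficients).
"""

from __future__ import annotations

from .parameters import LiverParams

__all__ = ["inhibited_mm_rate", "liver_derivatives", "liver_concentrations"]


def inhibited_mm_rate(CT_l: float, F_free: float, liver: LiverParams) -> float:
    """5aR1-mediated T -> DHT rate, nmol/hr, under competitive inhibition."""
    return liver.V_maxl * CT_l / (liver.K_m5a * (1.0 + F_free / liver.Ki_5aR1) + CT_l)


def liver_concentrations(AT_l: float, AD_l: float, liver: LiverParams) -> tuple[float, float]:
    """Free T and DHT concentrations in the liver, nM."""
    CT_l = AT_l / (liver.V_l * liver.PT_l)
    CD_l = AD_l / (liver.V_l * liver.PD_l)
    return CT_l, CD_l


def liver_derivatives(
    AT_l: float,
    AD_l: float,
    CT_bl: float,
    CD_bl: float,
    F_free: float,
    liver: LiverParams,
) -> tuple[float, float, float]:
    """Liver T and DHT amount derivatives, nmol/hr.

    Returns ``(dAT_l, dAD_l, mm_rate)``; every nmol of T metabolized appears
    as DHT (1:1 stoichiometry), so the same ``mm_rate`` leaves the T balance
    and enters the DHT balance.
    """
    CT_l, CD_l = liver_concentrations(AT_l, AD_l, liver)
    mm = inhibited_mm_rate(CT_l, F_free, liver)
    dAT_l = liver.Q_l * (CT_bl - CT_l) - mm - liver.k_lT * liver.V_l * CT_l
    dAD_l = liver.Q_l * (CD_bl - CD_l) + mm - liver.k_lD * liver.V_l * CD_l
    return dAT_l, dAD_l, mm
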