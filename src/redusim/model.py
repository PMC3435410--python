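"""Assembly of the full system derivative from the per-organ modules.

A :class:`RuntimeParams` object bundles a validated parameter set with the
forced constants of an intact steady state.  Building one recomputes the
derived kinetic identities (k2, k4) from their primary parameters, but
deliberately does *not* re-solve the steady-state forcings: sensitivity
analysis perturbs a single parameter of the calibrated model while holding
every forced constant at its baseline value, exactly as a finished model
implementation would behave.

Prostatic concentration species (5aR2 and AR species) carry a dilution
term ``-C * (dV_p/dt) / V_p`` because the prostate changes volume roughly
four-fold over three weeks; the term conserves species amounts under
volume change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import axis as axis_mod
from . import liver as liver_mod
from . import mass as mass_mod
from . import pk as pk_mod
from . import receptor as rec_mod
from .enzyme import enzyme_derivatives
from .forcing import MG_TO_L, ForcedConstants, force_steady_state
from .parameters import ModelParameters, validate_parameters
from .state import N_STATES, OBSERVABLE_NAMES, S

__all__ = ["RuntimeParams", "build_runtime", "assemble_derivative",
           "derivative_and_fluxes", "observables", "total_prostate_mass"]


@dataclass
class RuntimeParams:
    """Parameter set plus forced constants, ready for integration."""

    params: ModelParameters
    forced: ForcedConstants
    testes_on: bool = True

    def with_testes(self, on: bool) -> "RuntimeParams":
        return RuntimeParams(self.params, self.forced, testes_on=on)


def build_runtime(
    params: ModelParameters,
    testes_on: bool = True,
) -> tuple[RuntimeParams, np.ndarray]:
    """Validate ``params``, force the intact steady state, and return the
    runtime bundle together with the intact state vector.

    The sensitivity machinery instead constructs ``RuntimeParams`` directly
    from perturbed parameters plus the *baseline* forced constants and
    baseline initial state, so that a single-parameter perturbation does
    not silently re-calibrate the model.
    """
    validate_parameters(params)
    forced, x0 = force_steady_state(params)
    return RuntimeParams(params, forced, testes_on=testes_on), x0


def _core(t: float, y: np.ndarray, rp: RuntimeParams, want_fluxes: bool):
    p = rp.params
    fc = rp.forced
    lv, en, gn, ms, ax, pkp = p.liver, p.enzyme, p.gene, p.mass, p.axis, p.pk

    A1, A2, A3 = y[S.A1_F], y[S.A2_F], y[S.A3_F]
    AT_l, AD_l = y[S.AT_L], y[S.AD_L]
    AT_bl, AD_bl = y[S.AT_BL], y[S.AD_BL]
    AT_bd, AD_bd = y[S.AT_BD], y[S.AD_BD]
    LH = y[S.LH]
    AT_p, AD_p = y[S.AT_P], y[S.AD_P]
    E, ET, EF, EFstar = y[S.E], y[S.ET], y[S.EF], y[S.EFSTAR]
    AR, ART, ARD = y[S.AR], y[S.ART], y[S.ARD]
    VPC_1, VPL_1 = y[S.VPC_1], y[S.VPL_1]

    # geometry and flows
    V_p = mass_mod.total_prostate_mass(VPC_1, VPL_1, ms)      # mg
    V_pL = V_p * MG_TO_L                                      # L
    Q_p = fc.Qp0 * V_p / fc.V_p0                              # flow scales with mass
    PS_pD = fc.PS_pD0 * V_p / fc.V_p0                         # so does exchange area

    # algebraic concentrations
    F_free = pk_mod.free_central_concentration(A2, pkp)
    CT_bl = AT_bl / ax.V_bl
    CD_bl = AD_bl / ax.V_bl
    CT_pf = AT_p / (V_pL * ax.PT_p)
    CD_pf = AD_p / (V_pL * ax.PD_p)

    # gene occupancy (quasi-equilibrium)
    TT, TD, DD = rec_mod.dimer_concentrations(ART, ARD, gn)
    P = rec_mod.dimer_potency(TT, TD, DD, gn)
    occ = {}
    for g in rec_mod.GENES:
        Sg = P / fc.K_occ[g]
        occ[g] = Sg / (1.0 + Sg)

    # prostate masses (needed first: dilution of concentration species)
    dVPC_1, dVPL_1 = mass_mod.mass_derivatives(
        VPC_1, VPL_1, occ["cp"], occ["cd"], occ["sec"], ms, fc.k_cd1, fc.k_lum
    )
    gV = (dVPC_1 + dVPL_1) / V_p                              # relative volume growth, hr^-1

    # 5aR2 kinetics
    dE, dET, dEF, dEFstar, bT_enz, cat, bF = enzyme_derivatives(
        E, ET, EF, EFstar, CT_pf, F_free, occ["5aR2"], en, gn.DNAo_5aR20
    )
    dE -= gV * E
    dET -= gV * ET
    dEF -= gV * EF
    dEFstar -= gV * EFstar

    # androgen receptor
    dAR, dART, dARD, bT_ar, bD_ar = rec_mod.receptor_derivatives(
        AR, ART, ARD, CT_pf, CD_pf, gn, fc.kAR_syn
    )
    dAR -= gV * AR
    dART -= gV * ART
    dARD -= gV * ARD

    # prostatic androgen amounts; ligand in degraded complexes returns free
    dAT_p = (
        Q_p * (CT_bl - CT_pf)
        - bT_enz * V_pL
        - bT_ar * V_pL
        + gn.kAR_deg * ART * V_pL
    )
    dAD_p = (
        PS_pD * (CD_bl - CD_pf)
        + cat * V_pL
        - bD_ar * V_pL
        + gn.kAR_deg * ARD * V_pL
    )

    # liver
    dAT_l, dAD_l, mm = liver_mod.liver_derivatives(AT_l, AD_l, CT_bl, CD_bl, F_free, lv)
    CT_l, CD_l = liver_mod.liver_concentrations(AT_l, AD_l, lv)

    # blood, body, LH
    dAT_bl, dAD_bl, dAT_bd, dAD_bd, dLH = axis_mod.axis_derivatives(
        AT_bl, AD_bl, AT_bd, AD_bd, LH, CT_l, CD_l, CT_pf, CD_pf, Q_p, PS_pD,
        ax, lv.Q_l, fc.kLH_prod, fc.kT_prod, fc.CL_blD, rp.testes_on,
    )

    # finasteride PK with the prostatic 5aR2 sink
    dA1, dA2, dA3 = pk_mod.pk_derivative(A1, A2, A3, bF * V_pL, pkp)

    dy = np.empty(N_STATES)
    dy[S.A1_F], dy[S.A2_F], dy[S.A3_F] = dA1, dA2, dA3
    dy[S.AT_L], dy[S.AD_L] = dAT_l, dAD_l
    dy[S.AT_BL], dy[S.AD_BL] = dAT_bl, dAD_bl
    dy[S.AT_BD], dy[S.AD_BD] = dAT_bd, dAD_bd
    dy[S.LH] = dLH
    dy[S.AT_P], dy[S.AD_P] = dAT_p, dAD_p
    dy[S.E], dy[S.ET], dy[S.EF], dy[S.EFSTAR] = dE, dET, dEF, dEFstar
    dy[S.AR], dy[S.ART], dy[S.ARD] = dAR, dART, dARD
    dy[S.VPC_1], dy[S.VPL_1] = dVPC_1, dVPL_1

    if not want_fluxes:
        return dy

    fluxes = {
        # each inter-compartment transfer appears once; sign convention:
        # positive = into the named destination
        "flow_T_blood_to_liver": lv.Q_l * (CT_bl - CT_l),
        "flow_D_blood_to_liver": lv.Q_l * (CD_bl - CD_l),
        "flow_T_blood_to_body": ax.Q_bd * (CT_bl - AT_bd / ax.V_bd),
        "flow_D_blood_to_body": ax.Q_bd * (CD_bl - AD_bd / ax.V_bd),
        "flow_T_blood_to_prostate": Q_p * (CT_bl - CT_pf),
        "flow_D_blood_to_prostate": PS_pD * (CD_bl - CD_pf),
        "liver_mm_T_to_D": mm,
        "testes_T_production": fc.kT_prod * LH if rp.testes_on else 0.0,
        "blood_D_clearance": fc.CL_blD * CD_bl,
        "enzyme_T_binding_nmol": bT_enz * V_pL,
        "enzyme_D_production_nmol": cat * V_pL,
        "enzyme_F_binding_nmol": bF * V_pL,
        "ar_T_binding_nmol": bT_ar * V_pL,
        "ar_D_binding_nmol": bD_ar * V_pL,
        "ar_T_release_deg_nmol": gn.kAR_deg * ART * V_pL,
        "ar_D_release_deg_nmol": gn.kAR_deg * ARD * V_pL,
        "pk_elimination_nmol": pkp.k10 * A2,
        "enzyme_F_degradation_nmol": en.k_dg * (EF + EFstar) * V_pL,
    }
    return dy, fluxes


def assemble_derivative(t: float, y: np.ndarray, rp: RuntimeParams) -> np.ndarray:
    """Full system derivative d(state)/dt; raises on non-finite results."""
    dy = _core(t, y, rp, want_fluxes=False)
    if not np.all(np.isfinite(dy)):
        bad = [S(i).name for i in np.flatnonzero(~np.isfinite(dy))]
        raise FloatingPointError(f"non-finite derivative for state(s) {bad}")
    return dy


def rhs(t: float, y: np.ndarray, rp: RuntimeParams) -> np.ndarray:
    """Unchecked derivative (hot path for the integrator)."""
    return _core(t, y, rp, want_fluxes=False)


def derivative_and_fluxes(t: float, y: np.ndarray, rp: RuntimeParams):
    """Derivative plus a dictionary of named inter-compartment fluxes."""
    return _core(t, y, rp, want_fluxes=True)


def total_prostate_mass(y: np.ndarray, params: ModelParameters) -> float:
    """Total prostate mass (mg) for a state vector."""
    return mass_mod.total_prostate_mass(y[S.VPC_1], y[S.VPL_1], params.mass)


def observables(y: np.ndarray, rp: RuntimeParams) -> dict[str, float]:
    """Derived (algebraic) observables for one state vector."""
    p = rp.params
    fc = rp.forced
    gn, ms, ax, lv, pkp = p.gene, p.mass, p.axis, p.liver, p.pk

    V_p = mass_mod.total_prostate_mass(y[S.VPC_1], y[S.VPL_1], ms)
    V_pL = V_p * MG_TO_L
    CT_l, CD_l = liver_mod.liver_concentrations(y[S.AT_L], y[S.AD_L], lv)
    TT, TD, DD = rec_mod.dimer_concentrations(y[S.ART], y[S.ARD], gn)
    P = rec_mod.dimer_potency(TT, TD, DD, gn)
    occ = {g: (P / fc.K_occ[g]) / (1.0 + P / fc.K_occ[g]) for g in rec_mod.GENES}
    out = {
        "F_free": pk_mod.free_central_concentration(y[S.A2_F], pkp),
        "CT_l": CT_l,
        "CD_l": CD_l,
        "CT_bl": y[S.AT_BL] / ax.V_bl,
        "CD_bl": y[S.AD_BL] / ax.V_bl,
        "CT_pf": y[S.AT_P] / (V_pL * ax.PT_p),
        "CD_pf": y[S.AD_P] / (V_pL * ax.PD_p),
        "TT": TT,
        "TD": TD,
        "DD": DD,
        "DNAo_cp": occ["cp"],
        "DNAo_cd": occ["cd"],
        "DNAo_sec": occ["sec"],
        "DNAo_5aR2": occ["5aR2"],
        "V_p": V_p,
        "Q_p": fc.Qp0 * V_p / fc.V_p0,
        "total_mass": V_p,
    }
    assert tuple(out) == OBSERVABLE_NAMES
    return out
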