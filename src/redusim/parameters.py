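"""Model parameters, organized by organ/process, with validation.

Units are hours, nmol, nM, mg and litres throughout.  A mass of 1 mg of
ventral prostate tissue is treated as 1 uL of tissue volume everywhere.

Two kinds of constants are distinguished:

* *derived identities* (``k2 = Km*k1 - kcat``, ``k4 = Ki_5aR2*k3``) are
  recomputed from their primary parameters every time a runtime parameter
  set is built, so perturbing ``Km`` or ``Ki_5aR2`` propagates;
* *steady-state forcings* (prostate blood flow, testicular production,
  LH production, AR synthesis, gene half-saturation constants, death and
  lumen-clearance rate constants, 5aR2 synthesis scale) are solved once
  from the intact anchors by :mod:`redusim.forcing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict
from typing import Any

import math

__all__ = [
    "LiverParams",
    "EnzymeParams",
    "GeneRegParams",
    "MassParams",
    "AxisParams",
    "PKParams",
    "ModelParameters",
    "validate_parameters",
]


@dataclass
class LiverParams:
    """Hepatic flow, partitioning and 5aR1-mediated T -> DHT metabolism."""

    Q_l: float = 1.06        # blood flow to liver, L/hr
    V_maxl: float = 3.65     # max velocity of hepatic T metabolism, nmol/hr
    PT_l: float = 2.75       # T liver:plasma partition coefficient
    PD_l: float = 2.0        # DHT liver:plasma partition coefficient
    K_m5a: float = 2.3       # Km of hepatic 5aR1 for T, nM
    k_lT: float = 87.9       # nonspecific hepatic T elimination, hr^-1 (applied as k*V_l*C)
    k_lD: float = 77.2       # nonspecific hepatic DHT elimination, hr^-1 (applied as k*V_l*C)
    Ki_5aR1: float = 5.4     # finasteride inhibition constant on 5aR1, nM
    V_l: float = 0.005       # effective liver distribution volume, L (calibrated)


@dataclass
class EnzymeParams:
    """Prostatic 5aR2 mass-action kinetics and turnover."""

    k1: float = 500.0        # T:5aR2 association, hr^-1 nM^-1
    kcat: float = 270.0      # catalytic constant T -> DHT, hr^-1
    Km: float = 0.6          # Km of 5aR2 for T, nM
    k3: float = 1000.0       # finasteride:5aR2 association, hr^-1 nM^-1
    k5: float = 3.96         # isomerization to the inactivated complex, hr^-1
    k6: float = 0.0          # reverse isomerization, hr^-1 (approximately zero)
    Ki_5aR2: float = 0.5     # finasteride Ki on 5aR2, nM
    k_dg: float = 0.016      # 5aR2 degradation rate constant, hr^-1
    E_tot0: float = 20.0     # total 5aR2 at the intact steady state, nM
    E_free0: float = 19.0    # free 5aR2 at the intact steady state, nM

    @property
    def k2(self) -> float:
        """Dissociation rate constant of the 5aR2:T complex, hr^-1."""
        return derive_k2(self.Km, self.k1, self.kcat)

    @property
    def k4(self) -> float:
        """Dissociation rate constant of the 5aR2:finasteride complex, hr^-1."""
        return derive_k4(self.Ki_5aR2, self.k3)

    @property
    def ET0(self) -> float:
        """5aR2:T complex concentration at the intact steady state, nM."""
        return self.E_tot0 - self.E_free0


def derive_k2(Km: float, k1: float, kcat: float) -> float:
    """``k2 = Km*k1 - kcat`` (Segal relation for an irreversible catalytic step)."""
    k2 = Km * k1 - kcat
    if k2 <= 0:
        raise ValueError(
            f"k2 = Km*k1 - kcat must be positive (Km*k1 = {Km * k1}, kcat = {kcat})"
        )
    return k2


def derive_k4(Ki_5aR2: float, k3: float) -> float:
    """``k4 = Ki_5aR2 * k3`` (definition of the competitive Ki)."""
    if Ki_5aR2 <= 0 or k3 <= 0:
        raise ValueError("Ki_5aR2 and k3 must be positive")
    return Ki_5aR2 * k3


@dataclass
class GeneRegParams:
    """AR ligand binding, dimerization and gene-occupancy parameters.

    The AR:ligand rate constants and the dimer association constant are not
    experimentally anchored; they are calibrated so that the intact state
    reproduces the occupancy anchors and the treated arm reproduces the
    published extent of prostate regression (see docs/methods.md).
    """

    konT: float = 0.1        # AR + T association, hr^-1 nM^-1
    koffT: float = 12.0      # AR:T dissociation, hr^-1 (calibrated; effective KdT ~ 122 nM)
    konD: float = 1.0        # AR + DHT association, hr^-1 nM^-1
    koffD: float = 60.0      # AR:DHT dissociation, hr^-1 (calibrated; effective KdD ~ 60 nM)
    kAR_deg: float = 0.231   # AR species degradation, hr^-1 (3 h half-life)
    AR_free0: float = 2.0    # free AR at the intact steady state, nM
    kdim: float = 0.02       # quasi-equilibrium dimer association constant, nM^-1
    k_DNAoffTT: float = 1.6  # divisor on TT-dimer DNA potency (relative potency)
    w_TD: float = 1.0 / math.sqrt(1.6)  # TD-dimer potency weight (geometric mean)
    DNAo_cp0: float = 0.95   # intact occupancy anchor, cell proliferation gene
    DNAo_cd0: float = 0.95   # intact occupancy anchor, anti-apoptosis gene
    DNAo_sec0: float = 0.95  # intact occupancy anchor, fluid production gene
    DNAo_5aR20: float = 0.95  # intact occupancy anchor, 5aR2 gene


@dataclass
class MassParams:
    """Androgen-sensitive and basal prostate mass compartments."""

    k_cp1: float = 0.5       # cell proliferation rate constant, mg/hr
    VPC_1b: float = 191.0    # intact androgen-sensitive cellular mass, mg
    VPC_2: float = 18.0      # basal cellular mass, mg
    VPL_2: float = 18.2      # basal ductal lumen mass, mg
    V_p_total0: float = 457.0  # intact total prostate mass, mg
    k_sec: float = 5.0       # fluid production rate constant, mg/hr

    @property
    def VPL_1b(self) -> float:
        """Intact androgen-sensitive lumen mass, mg (closes the 457 mg total)."""
        return self.V_p_total0 - self.VPC_1b - self.VPC_2 - self.VPL_2


@dataclass
class AxisParams:
    """Blood/body PBPK, prostate partitioning and the LH feedback loop."""

    CT_bl0: float = 6.0      # intact blood T anchor, nM
    CD_bl0: float = 0.3      # intact blood DHT anchor, nM
    LH0: float = 1.0         # normalized intact LH level
    V_bl: float = 0.022      # blood volume, L
    V_bd: float = 0.25       # lumped body volume, L
    Q_bd: float = 5.0        # blood flow to the lumped body, L/hr
    PT_p: float = 2.0        # nonspecific T prostate partition coefficient
    PD_p: float = 2.0        # nonspecific DHT prostate partition coefficient
    CD_pf0: float = 30.0     # intact free prostatic DHT anchor, nM (sets the
                             # forced, diffusion-limited DHT efflux coefficient)
    n_hill: float = 2.0      # Hill coefficient of androgen feedback on LH
    K_inh: float = 6.3       # androgen inhibition constant on LH production, nM
    kLH_deg: float = 1.4     # LH degradation rate constant, hr^-1


@dataclass
class PKParams:
    """Two-compartment oral finasteride PK (first-order absorption)."""

    ka: float = 1.0          # absorption rate constant, hr^-1
    k10: float = 0.45        # central elimination rate constant, hr^-1 (alpha t1/2 ~ 1.6 h)
    k12: float = 0.004       # central -> deep peripheral, hr^-1 (~1% of each dose)
    k21: float = 0.02        # deep peripheral -> central, hr^-1 (beta t1/2 ~ 35 h)
    Vc: float = 0.25         # central volume of distribution, L
    fu: float = 0.10         # unbound fraction in plasma
    MW_F: float = 372.55     # finasteride molecular weight, g/mol
    BW: float = 0.35         # body weight, kg


@dataclass
class ModelParameters:
    """Aggregate of all parameter sections."""

    liver: LiverParams = field(default_factory=LiverParams)
    enzyme: EnzymeParams = field(default_factory=EnzymeParams)
    gene: GeneRegParams = field(default_factory=GeneRegParams)
    mass: MassParams = field(default_factory=MassParams)
    axis: AxisParams = field(default_factory=AxisParams)
    pk: PKParams = field(default_factory=PKParams)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            liver=replace(self.liver),
            enzyme=replace(self.enzyme),
            gene=replace(self.gene),
            mass=replace(self.mass),
            axis=replace(self.axis),
            pk=replace(self.pk),
        )

    def to_dict(self) -> dict[str, dict[str, float]]:
        return asdict(self)

    def get(self, name: str) -> float:
        """Look up a scalar parameter by bare name across all sections."""
        section, f = self._locate(name)
        return getattr(getattr(self, section), f)

    def set(self, name: str, value: float) -> None:
        section, f = self._locate(name)
        setattr(getattr(self, section), f, value)

    def _locate(self, name: str) -> tuple[str, str]:
        hits = []
        for sec in fields(self):
            obj = getattr(self, sec.name)
            if any(f.name == name for f in fields(obj)):
                hits.append((sec.name, name))
        if not hits:
            raise KeyError(f"unknown parameter {name!r}")
        if len(hits) > 1:
            raise KeyError(f"ambiguous parameter name {name!r}: {hits}")
        return hits[0]


_POSITIVE = {
    "liver": ["Q_l", "V_maxl", "PT_l", "PD_l", "K_m5a", "k_lT", "k_lD", "Ki_5aR1", "V_l"],
    "enzyme": ["k1", "kcat", "Km", "k3", "k5", "Ki_5aR2", "k_dg", "E_tot0", "E_free0"],
    "gene": ["konT", "koffT", "konD", "koffD", "kAR_deg", "AR_free0", "kdim",
             "k_DNAoffTT", "w_TD"],
    "mass": ["k_cp1", "VPC_1b", "VPC_2", "VPL_2", "V_p_total0", "k_sec"],
    "axis": ["CT_bl0", "CD_bl0", "LH0", "V_bl", "V_bd", "Q_bd", "PT_p", "PD_p",
             "CD_pf0", "n_hill", "K_inh", "kLH_deg"],
    "pk": ["ka", "k10", "k12", "k21", "Vc", "MW_F", "BW"],
}

_NONNEGATIVE = {"enzyme": ["k6"]}

_ANCHORS = ["DNAo_cp0", "DNAo_cd0", "DNAo_sec0", "DNAo_5aR20"]


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Check every structural invariant; return the (unmodified) parameters.

    Raises ``ValueError`` naming the offending parameter.  Checks include
    positivity, the (0, 1) range of occupancy anchors and the unbound
    fraction, the Segal identity ``k2 > 0``, the steady-state enzyme
    partition ``E_free0 < E_tot0``, and that the intact total mass anchor
    exceeds the basal plus cellular compartments.
    """
    for section, names in _POSITIVE.items():
        obj = getattr(params, section)
        for name in names:
            if not getattr(obj, name) > 0:
                raise ValueError(f"{section}.{name} must be > 0, got {getattr(obj, name)}")
    for section, names in _NONNEGATIVE.items():
        obj = getattr(params, section)
        for name in names:
            if getattr(obj, name) < 0:
                raise ValueError(f"{section}.{name} must be >= 0")
    if not 0 < params.pk.fu <= 1:
        raise ValueError(f"pk.fu must lie in (0, 1], got {params.pk.fu}")
    for name in _ANCHORS:
        v = getattr(params.gene, name)
        if not 0 < v < 1:
            raise ValueError(f"gene.{name} must lie strictly in (0, 1), got {v}")
    # derived identities must be well defined
    derive_k2(params.enzyme.Km, params.enzyme.k1, params.enzyme.kcat)
    derive_k4(params.enzyme.Ki_5aR2, params.enzyme.k3)
    if not params.enzyme.ET0 > 0:
        raise ValueError("enzyme.E_free0 must be smaller than enzyme.E_tot0")
    if params.mass.VPL_1b <= 0:
        raise ValueError(
            "mass.V_p_total0 must exceed VPC_1b + VPC_2 + VPL_2 "
            f"(VPL_1b = {params.mass.VPL_1b})"
        )
    if params.axis.CT_bl0 <= params.enzyme.Km * params.enzyme.ET0 / params.enzyme.E_free0:
        raise ValueError("axis.CT_bl0 must exceed the intact free prostatic T level")
    if params.axis.CD_pf0 <= params.axis.CD_bl0:
        raise ValueError("axis.CD_pf0 must exceed axis.CD_bl0 (prostate exports DHT)")
    return params
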