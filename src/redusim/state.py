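"""State-vector layout for the whole-body model.

The ODE state is a flat ``numpy`` vector whose ordering is frozen here and
nowhere else.  Amount-type entries (finasteride and androgen pools) are in
nmol, prostatic protein species in nM, the androgen-sensitive prostate
compartments in mg, and LH in units normalized to its intact steady state.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class S(IntEnum):
    """Canonical index of every state variable."""

    # finasteride two-compartment PK (amounts, nmol)
    A1_F = 0          # gut depot
    A2_F = 1          # central compartment
    A3_F = 2          # peripheral compartment
    # liver androgens (amounts, nmol)
    AT_L = 3
    AD_L = 4
    # blood androgens (amounts, nmol)
    AT_BL = 5
    AD_BL = 6
    # lumped body androgens (amounts, nmol)
    AT_BD = 7
    AD_BD = 8
    # luteinizing hormone (normalized)
    LH = 9
    # prostatic androgens, free + nonspecifically bound (amounts, nmol)
    AT_P = 10
    AD_P = 11
    # prostatic 5aR2 species (concentrations, nM)
    E = 12            # free 5aR2
    ET = 13           # 5aR2:T complex
    EF = 14           # reversible 5aR2:finasteride complex
    EFSTAR = 15       # time-dependently (quasi-irreversibly) inhibited 5aR2
    # androgen receptor species (concentrations, nM)
    AR = 16
    ART = 17          # AR:T monomer
    ARD = 18          # AR:DHT monomer
    # androgen-sensitive prostate masses (mg)
    VPC_1 = 19        # cellular
    VPL_1 = 20        # ductal lumen


N_STATES = len(S)

#: Column names used for trajectory CSV output (order matches :class:`S`).
STATE_NAMES: tuple[str, ...] = tuple(s.name for s in S)

#: Names of the derived (algebraic) observables appended to trajectories.
OBSERVABLE_NAMES: tuple[str, ...] = (
    "F_free",
    "CT_l", "CD_l",
    "CT_bl", "CD_bl",
    "CT_pf", "CD_pf",
    "TT", "TD", "DD",
    "DNAo_cp", "DNAo_cd", "DNAo_sec", "DNAo_5aR2",
    "V_p", "Q_p", "total_mass",
)


def new_state() -> np.ndarray:
    """Return a zeroed state vector of the canonical length."""
    return np.zeros(N_STATES)


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    """Map a state vector to ``{name: value}`` (serialization round-trip)."""
    return {name: float(y[i]) for i, name in enumerate(STATE_NAMES)}


def state_from_dict(d: dict[str, float]) -> np.ndarray:
    """Inverse of :func:`state_to_dict`; unknown or missing keys raise."""
    extra = set(d) - set(STATE_NAMES)
    if extra:
        raise KeyError(f"unknown state entries: {sorted(extra)}")
    missing = set(STATE_NAMES) - set(d)
    if missing:
        raise KeyError(f"missing state entries: {sorted(missing)}")
    return np.array([d[name] for name in STATE_NAMES], dtype=float)
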