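"""Two-compartment oral finasteride pharmacokinetics.

A gut depot (A1) empties first-order into a central compartment (A2) that
exchanges with a peripheral compartment (A3) and is cleared first-order.
Only the unbound central concentration ``F_free = fu * A2 / Vc`` is
pharmacologically active; free drug is assumed to equilibrate instantly
with the well-perfused liver and prostate, so ``F_free`` serves as the free
inhibitor concentration in both tissues.  Binding of finasteride to
prostatic 5aR2 removes drug from the central compartment (a sink flux
supplied by the enzyme module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import PKParams

__all__ = ["DoseEvent", "DoseRegimen", "pk_derivative", "free_central_concentration",
           "dose_to_nmol"]


@dataclass(frozen=True)
class DoseEvent:
    """A single oral bolus."""

    time: float          # hr
    dose: float          # mg/kg
    route: str = "oral"

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.route != "oral":
            raise ValueError(f"unsupported route {self.route!r}")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: ``n_doses`` boluses every ``interval_hr`` hours."""

    dose_mg_per_kg: float = 40.0
    interval_hr: float = 24.0
    duration_days: float = 21.0
    washout_days: float = 0.0
    start_hr: float = 0.0

    def __post_init__(self):
        if self.dose_mg_per_kg < 0 or self.interval_hr <= 0 or self.duration_days <= 0:
            raise ValueError("regimen requires dose >= 0, interval > 0, duration > 0")
        if self.washout_days < 0:
            raise ValueError("washout_days must be >= 0")

    @property
    def n_doses(self) -> int:
        """Number of boluses administered within the dosing period."""
        import math
        return int(math.floor((self.duration_days * 24.0 - 1e-9) / self.interval_hr)) + 1

    @property
    def t_end_hr(self) -> float:
        return (self.duration_days + self.washout_days) * 24.0

    def events(self, pk: PKParams) -> list[DoseEvent]:
        return [
            DoseEvent(time=self.start_hr + i * self.interval_hr, dose=self.dose_mg_per_kg)
            for i in range(self.n_doses)
        ]


def dose_to_nmol(dose_mg_per_kg: float, BW_kg: float, MW_g_per_mol: float) -> float:
    """Convert an oral dose in mg/kg to nmol of drug for a given body weight."""
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    if BW_kg <= 0 or MW_g_per_mol <= 0:
        raise ValueError("body weight and molecular weight must be > 0")
    # mg/kg * kg = mg; mg / (g/mol) = mmol; * 1e6 -> nmol
    return dose_mg_per_kg * BW_kg / MW_g_per_mol * 1e6


def free_central_concentration(A2_nmol: float, pk: PKParams) -> float:
    """Unbound finasteride concentration in the central compartment, nM."""
    if pk.Vc <= 0:
        raise ValueError("Vc must be > 0")
    return pk.fu * A2_nmol / pk.Vc


def pk_derivative(
    A1: float,
    A2: float,
    A3: float,
    prostate_binding_flux: float,
    pk: PKParams,
) -> tuple[float, float, float]:
    """Time derivatives of the three finasteride amounts (nmol/hr).

    ``prostate_binding_flux`` is the net nmol/hr drawn from the central
    compartment by reversible binding to prostatic 5aR2,
    ``(k3*F_free*E - k4*EF) * V_p``.
    """
    dA1 = -pk.ka * A1
    dA2 = pk.ka * A1 - (pk.k10 + pk.k12) * A2 + pk.k21 * A3 - prostate_binding_flux
    dA3 = pk.k12 * A2 - pk.k21 * A3
    return dA1, dA2, dA3
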