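"""Calibration against (synthetic) three-arm study data.

The fixture generator emulates the calibration study design: intact,
castrated and finasteride-treated (40 mg/kg once daily for 21 days) rats
sampled at days 4, 9, 14 and 21 (plus day 0), measuring free prostatic T
and DHT concentrations and total prostate mass.  Because the original
measurements are not printed, fixtures are produced by simulating the
model itself and applying multiplicative lognormal noise — they exercise
the estimation machinery, not the historical data.

Fitting is unweighted least squares on log-scale residuals.  Each free
parameter is matched, by default, against the data subset that identifies
it in the study design: the 5aR2 degradation rate against treated
prostatic DHT, the TT-dimer DNA potency against treated prostate mass,
and the proliferation rate and basal masses against castrate prostate
mass.  Every candidate evaluation reconstructs the forced steady state, so
the calibration explores models that all honor the intact anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import build_runtime
from .parameters import ModelParameters
from .pk import DoseRegimen
from .simulate import Scenario, simulate

__all__ = ["generate_fixture", "calibrate", "CalibrationResult", "kdg_km_tradeoff"]

ARMS = ("intact", "castrate", "treated")
FIXTURE_OBSERVABLES = ("CT_pf", "CD_pf", "V_p")
DEFAULT_DAYS = (0, 4, 9, 14, 21)

#: Which (arm, observable) subset identifies each fittable parameter.
TARGET_MAP: dict[str, list[tuple[str, str]]] = {
    "k_dg": [("treated", "CD_pf")],
    "k_DNAoffTT": [("treated", "V_p")],
    "k_cp1": [("castrate", "V_p")],
    "VPC_2": [("castrate", "V_p")],
    "VPL_2": [("castrate", "V_p")],
}

_SCENARIOS = {
    "intact": lambda: Scenario(kind="intact"),
    "castrate": lambda: Scenario(kind="castration"),
    "treated": lambda: Scenario(
        kind="treated",
        regimen=DoseRegimen(dose_mg_per_kg=40.0, interval_hr=24.0, duration_days=21.0),
    ),
}


def _arm_predictions(params: ModelParameters, arms, days) -> dict[str, dict]:
    out: dict[str, dict] = {}
    rp, x0 = build_runtime(params)
    t_end = max(days) * 24.0 if max(days) > 0 else 24.0
    for arm in arms:
        res = simulate(_SCENARIOS[arm](), params, t_end_hr=t_end, dt_out=4.0,
                       runtime=rp, x0=x0)
        out[arm] = {
            obs: {d: res.observable_at(obs, d * 24.0) for d in days}
            for obs in FIXTURE_OBSERVABLES
        }
    return out


def generate_fixture(
    params: ModelParameters | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    days=DEFAULT_DAYS,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate the three study arms and add multiplicative lognormal noise.

    Columns: ``arm, day, observable, value, replicate``.  ``noise_cv`` is
    the coefficient of variation of the lognormal factor (0 = noise-free);
    the generator is fully reproducible from ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if params is None:
        params = ModelParameters()
    rng = np.random.default_rng(seed)
    truth = _arm_predictions(params, ARMS, days)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for arm in ARMS:
        for obs in FIXTURE_OBSERVABLES:
            for d in days:
                mu = truth[arm][obs][d]
                for rep in range(n_replicates):
                    factor = 1.0 if sigma == 0 else np.exp(
                        rng.normal(-0.5 * sigma**2, sigma)
                    )
                    rows.append({
                        "arm": arm, "day": d, "observable": obs,
                        "value": mu * factor, "replicate": rep,
                    })
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Fitted values, uncertainty estimates and residual diagnostics."""

    fitted: dict[str, float]
    se: dict[str, float]
    residual_norm: float
    n_residuals: int
    success: bool
    flat_parameters: list[str] = field(default_factory=list)
    message: str = ""

    def to_report(self) -> dict:
        return {
            "parameters": [
                {"parameter": k, "fitted": v, "se": self.se.get(k, float("nan"))}
                for k, v in self.fitted.items()
            ],
            "residual_norm": self.residual_norm,
            "n_residuals": self.n_residuals,
            "success": self.success,
            "flat_parameters": self.flat_parameters,
            "message": self.message,
        }


def calibrate(
    fixture_data: pd.DataFrame,
    free_param_names,
    params: ModelParameters | None = None,
    targets: list[tuple[str, str]] | None = None,
    x_rtol: float = 1e-4,
) -> CalibrationResult:
    """Least-squares fit of the named free parameters to fixture data.

    ``targets`` restricts the objective to (arm, observable) pairs; by
    default it is the union of each free parameter's identifying subset
    (all data if a parameter has no default mapping).  Parameters are
    optimized on a log scale; a parameter whose objective gradient is
    numerically flat is reported in ``flat_parameters``.
    """
    free_param_names = list(free_param_names)
    if params is None:
        params = ModelParameters()
    if targets is None:
        targets = []
        for name in free_param_names:
            targets.extend(TARGET_MAP.get(name, []))
        if not targets:
            targets = [(a, o) for a in ARMS for o in FIXTURE_OBSERVABLES]
        targets = sorted(set(targets))

    data = fixture_data.merge(
        pd.DataFrame(targets, columns=["arm", "observable"]), on=["arm", "observable"]
    )
    data = data[data["value"] > 0]
    if data.empty:
        raise ValueError("no fixture rows match the calibration targets")
    arms = sorted(data["arm"].unique())
    days = sorted(data["day"].unique())

    x0 = np.log([params.get(n) for n in free_param_names])

    def residuals(x: np.ndarray) -> np.ndarray:
        cand = params.copy()
        for name, v in zip(free_param_names, np.exp(x)):
            cand.set(name, float(v))
        pred = _arm_predictions(cand, arms, days)
        r = np.empty(len(data))
        for i, row in enumerate(data.itertuples(index=False)):
            mu = pred[row.arm][row.observable][row.day]
            r[i] = np.log(max(mu, 1e-12)) - np.log(row.value)
        return r

    sol = least_squares(residuals, x0, xtol=x_rtol, ftol=1e-8, method="lm"
                        if len(x0) <= len(data) else "trf")

    fitted = {n: float(v) for n, v in zip(free_param_names, np.exp(sol.x))}
    J = sol.jac
    se = {}
    flat = []
    dof = max(len(data) - len(x0), 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = J.T @ J
    for i, name in enumerate(free_param_names):
        if np.linalg.norm(J[:, i]) < 1e-8:
            flat.append(name)
            se[name] = float("inf")
        else:
            cov = np.linalg.pinv(JTJ) * s2
            # delta method back to natural scale
            se[name] = float(np.sqrt(max(cov[i, i], 0.0)) * fitted[name])
    return CalibrationResult(
        fitted=fitted,
        se=se,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_residuals=len(data),
        success=bool(sol.success),
        flat_parameters=flat,
        message=sol.message,
    )


def kdg_km_tradeoff(
    fixture_data: pd.DataFrame,
    Km_values,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Refit the 5aR2 degradation rate at fixed Km values.

    Exposes the sloppiness between the Michaelis constant and the enzyme
    degradation rate: near-identical fits to treated prostatic DHT data
    can be obtained for a range of Km by compensating with k_dg.
    """
    if params is None:
        params = ModelParameters()
    rows = []
    for Km in Km_values:
        p = params.copy()
        p.enzyme.Km = float(Km)
        fit = calibrate(fixture_data, ["k_dg"], params=p)
        rows.append({
            "Km": float(Km),
            "k_dg_fitted": fit.fitted["k_dg"],
            "residual_norm": fit.residual_norm,
        })
    return pd.DataFrame(rows)
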