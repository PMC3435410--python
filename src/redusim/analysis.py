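"""Sensitivity and dose-regimen analysis.

Control coefficients are normalized forward finite-difference
sensitivities ``CCA = [(x(1.01 p) - x(p)) / x(p)] / 0.01`` of an end-point
observable (default: sampled at hour 504, the instant of day 21 of a
40 mg/kg once-daily regimen, pre-dose) with respect to a +1% parameter
perturbation.  Both runs start from the same baseline steady-state
initialization, and the perturbation does not re-solve the steady-state
forcings — it probes the calibrated model as-is.  Derived kinetic
identities (k2 = Km*k1 - kcat, k4 = Ki*k3) do propagate, so perturbing Km
or Ki_5aR2 has the mechanistic effect of shifting the corresponding
dissociation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import RuntimeParams, build_runtime
from .parameters import ModelParameters
from .pk import DoseRegimen
from .simulate import Scenario, SimulationResult, simulate
from .state import OBSERVABLE_NAMES, STATE_NAMES

__all__ = [
    "DEFAULT_REGIMEN",
    "SensitivityReport",
    "SurfaceGrid",
    "control_coefficient",
    "sensitivity_report",
    "dose_frequency_surface",
    "normalized_signal",
]

DEFAULT_REGIMEN = DoseRegimen(dose_mg_per_kg=40.0, interval_hr=24.0, duration_days=21.0)

#: (parameter, observable) pairs analyzed by default: the new/changed
#: constants against the end points they plausibly control, plus the three
#: binding rate constants the model is expected to be insensitive to.
DEFAULT_SENSITIVITY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Km", "CD_pf"),
    ("k_dg", "CD_pf"),
    ("K_m5a", "CT_bl"),
    ("K_m5a", "CD_bl"),
    ("K_m5a", "CT_pf"),
    ("K_m5a", "V_p"),
    ("k5", "CD_pf"),
    ("kcat", "CD_pf"),
    ("Ki_5aR2", "CD_pf"),
    ("Ki_5aR1", "CD_bl"),
    ("k_DNAoffTT", "DNAo_cd"),
    ("k_DNAoffTT", "DNAo_sec"),
    ("k_DNAoffTT", "DNAo_cp"),
    ("k_DNAoffTT", "V_p"),
    ("k1", "CD_pf"),
    ("k3", "CD_pf"),
    ("k6", "CD_pf"),
)


@dataclass
class SensitivityReport:
    """Control coefficients per (parameter, observable) pair."""

    entries: list[dict] = field(default_factory=list)
    regimen: DoseRegimen = DEFAULT_REGIMEN
    delta_fraction: float = 0.01

    def value(self, parameter: str, observable: str) -> float:
        for e in self.entries:
            if e["parameter"] == parameter and e["observable"] == observable:
                return e["CCA"]
        raise KeyError((parameter, observable))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def _endpoint(result: SimulationResult, observable: str, t_hr: float) -> float:
    if observable in OBSERVABLE_NAMES:
        return result.observable_at(observable, t_hr)
    if observable in STATE_NAMES:
        i = int(np.argmin(np.abs(result.time_hr - t_hr)))
        return float(result.state(observable)[i])
    raise KeyError(f"unknown observable {observable!r}")


def _end_time(regimen: DoseRegimen) -> float:
    return regimen.duration_days * 24.0


def control_coefficient(
    param_name: str,
    observable_name: str,
    params: ModelParameters | None = None,
    regimen: DoseRegimen = DEFAULT_REGIMEN,
    delta: float = 0.01,
    _baseline: tuple[RuntimeParams, np.ndarray, SimulationResult] | None = None,
) -> float:
    """Forward finite-difference control coefficient of one observable."""
    if params is None:
        params = ModelParameters()
    scenario = Scenario(kind="treated", regimen=regimen)
    t_end = _end_time(regimen)
    if _baseline is None:
        rp, x0 = build_runtime(params)
        base = simulate(scenario, params, t_end_hr=t_end, runtime=rp, x0=x0)
    else:
        rp, x0, base = _baseline
    x_base = _endpoint(base, observable_name, t_end)
    if x_base == 0.0:
        raise ZeroDivisionError(
            f"baseline {observable_name} is zero at t = {t_end} hr; "
            "control coefficient undefined"
        )

    pert = rp.params.copy()
    p0 = pert.get(param_name)
    if p0 == 0.0:
        # a zero-valued rate (e.g. k6) perturbed multiplicatively stays zero
        return 0.0
    pert.set(param_name, p0 * (1.0 + delta))
    rp_pert = RuntimeParams(pert, rp.forced, testes_on=rp.testes_on)
    res = simulate(scenario, pert, t_end_hr=t_end, runtime=rp_pert, x0=x0)
    x_pert = _endpoint(res, observable_name, t_end)
    return ((x_pert - x_base) / x_base) / delta


def sensitivity_report(
    params: ModelParameters | None = None,
    pairs: Sequence[tuple[str, str]] = DEFAULT_SENSITIVITY_PAIRS,
    regimen: DoseRegimen = DEFAULT_REGIMEN,
    delta: float = 0.01,
) -> SensitivityReport:
    """Control coefficients for many pairs, sharing one baseline run and one
    perturbed run per distinct parameter."""
    if params is None:
        params = ModelParameters()
    scenario = Scenario(kind="treated", regimen=regimen)
    t_end = _end_time(regimen)
    rp, x0 = build_runtime(params)
    base = simulate(scenario, params, t_end_hr=t_end, runtime=rp, x0=x0)

    runs: dict[str, SimulationResult | None] = {}
    for pname in {p for p, _ in pairs}:
        pert = params.copy()
        p0 = pert.get(pname)
        if p0 == 0.0:
            runs[pname] = None
            continue
        pert.set(pname, p0 * (1.0 + delta))
        rp_pert = RuntimeParams(pert, rp.forced, testes_on=rp.testes_on)
        runs[pname] = simulate(scenario, pert, t_end_hr=t_end, runtime=rp_pert, x0=x0)

    report = SensitivityReport(regimen=regimen, delta_fraction=delta)
    for pname, oname in pairs:
        x_base = _endpoint(base, oname, t_end)
        if x_base == 0.0:
            raise ZeroDivisionError(f"baseline {oname} is zero; CCA undefined")
        run = runs[pname]
        cca = 0.0 if run is None else ((_endpoint(run, oname, t_end) - x_base) / x_base) / delta
        report.entries.append({"parameter": pname, "observable": oname, "CCA": cca})
    return report


def _default_doses() -> np.ndarray:
    return 10.0 ** (-3.0 + 0.5 * np.arange(13))


def _default_intervals() -> np.ndarray:
    return np.arange(6.0, 121.0, 6.0)


@dataclass
class SurfaceGrid:
    """End-of-treatment prostate mass over a dose x dosing-interval grid."""

    doses: np.ndarray                 # mg/kg
    intervals: np.ndarray             # hr
    V_end: np.ndarray                 # mg, shape (n_doses, n_intervals); NaN = failed cell
    duration_days: float = 21.0

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = [
            {"dose_mg_per_kg": d, "interval_hr": i, "V_end_mg": self.V_end[a, b]}
            for a, d in enumerate(self.doses)
            for b, i in enumerate(self.intervals)
        ]
        return pd.DataFrame(rows)

    def to_matrix_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.V_end,
            index=pd.Index(self.doses, name="dose_mg_per_kg"),
            columns=pd.Index(self.intervals, name="interval_hr"),
        )


def dose_frequency_surface(
    params: ModelParameters | None = None,
    doses: Iterable[float] | None = None,
    intervals: Iterable[float] | None = None,
    duration_days: float = 21.0,
) -> SurfaceGrid:
    """Total prostate mass at the end of a dosing period for every regimen
    on the grid.  Cells are independent; a solver failure marks its cell
    NaN and leaves the rest intact."""
    if params is None:
        params = ModelParameters()
    doses = _default_doses() if doses is None else np.asarray(list(doses), dtype=float)
    intervals = (
        _default_intervals() if intervals is None
        else np.asarray(list(intervals), dtype=float)
    )
    if doses.size == 0 or intervals.size == 0 or (doses < 0).any() or (intervals <= 0).any():
        raise ValueError("doses must be >= 0 and intervals > 0, both nonempty")

    rp, x0 = build_runtime(params)
    t_end = duration_days * 24.0
    V = np.full((doses.size, intervals.size), np.nan)
    for a, d in enumerate(doses):
        for b, tau in enumerate(intervals):
            regimen = DoseRegimen(dose_mg_per_kg=float(d), interval_hr=float(tau),
                                  duration_days=duration_days)
            scenario = Scenario(kind="treated", regimen=regimen)
            try:
                res = simulate(scenario, params, t_end_hr=t_end, dt_out=6.0,
                               runtime=rp, x0=x0)
            except RuntimeError:
                continue
            V[a, b] = res.observable_at("V_p", t_end)
    return SurfaceGrid(doses=doses, intervals=intervals, V_end=V,
                       duration_days=duration_days)


def normalized_signal(
    CT_pf: np.ndarray,
    CD_pf: np.ndarray,
    params: ModelParameters,
    time_hr: np.ndarray | None = None,
    window_hr: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float | None]:
    """AR-affinity-normalized total androgen signal.

    ``signal(t) = CT_pf(t)/KdT + CD_pf(t)/KdD`` with the binding
    dissociation constants ``KdT = koffT/konT``, ``KdD = koffD/konD``.
    Returns the signal trajectory and, if ``time_hr``/``window_hr`` are
    given, its time average over the window.
    """
    CT_pf = np.asarray(CT_pf, dtype=float)
    CD_pf = np.asarray(CD_pf, dtype=float)
    if CT_pf.shape != CD_pf.shape:
        raise ValueError("trajectories must be aligned on one grid")
    g = params.gene
    signal = CT_pf / (g.koffT / g.konT) + CD_pf / (g.koffD / g.konD)
    mean = None
    if time_hr is not None and window_hr is not None:
        t = np.asarray(time_hr, dtype=float)
        m = (t >= window_hr[0]) & (t <= window_hr[1])
        if m.sum() < 2:
            raise ValueError("window contains fewer than two samples")
        mean = float(np.trapezoid(signal[m], t[m]) / (t[m][-1] - t[m][0]))
    return signal, mean
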