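"""Steady-state initialization and stiff scenario integration."""

import numpy as np
import pytest

from redusim import (
    DoseRegimen,
    ModelParameters,
    Scenario,
    initialize_steady_state,
    simulate,
)
from redusim.state import OBSERVABLE_NAMES, S, STATE_NAMES


class TestInitialization:
    def test_enzyme_partition_matches_predictions(self, runtime):
        rp, x0 = runtime
        assert x0[S.E] == pytest.approx(19.0)
        assert x0[S.ET] == pytest.approx(1.0)
        assert x0[S.EF] == 0.0 and x0[S.EFSTAR] == 0.0

    def test_intact_total_mass(self, runtime):
        rp, x0 = runtime
        assert x0[S.VPC_1] + 18.0 + x0[S.VPL_1] + 18.2 == pytest.approx(457.0)

    def test_initializer_agrees_with_forcing(self, params):
        rp, x0 = initialize_steady_state(params)
        assert x0[S.E] == pytest.approx(19.0)

    def test_local_stability_of_intact_state(self, runtime, params):
        """A +1% whole-state perturbation relaxes back; the slowest mode is
        the androgen-sensitive cellular mass (half-time ~17 days), so a
        1500 h drug-free run must return within 0.1%."""
        rp, x0 = runtime
        res = simulate(Scenario("intact"), params, t_end_hr=1500.0, dt_out=25.0,
                       runtime=rp, x0=x0 * 1.01)
        rel = np.abs(res.states[-1] - x0) / np.maximum(np.abs(x0), 1e-12)
        assert rel.max() < 1e-3


class TestIntegration:
    def test_intact_scenario_is_stationary_for_21_days(self, params, runtime):
        rp, x0 = runtime
        res = simulate(Scenario("intact"), params, dt_out=12.0, runtime=rp, x0=x0)
        rel = np.abs(res.states - x0) / np.maximum(np.abs(x0), 1e-12)
        assert rel.max() < 1e-3

    def test_castration_reaches_basal_mass(self, params, runtime):
        rp, x0 = runtime
        res = simulate(Scenario("castration"), params, dt_out=6.0, runtime=rp, x0=x0)
        V = res.observable("V_p")
        assert V[-1] == pytest.approx(36.2, abs=0.2)
        assert np.all(np.diff(V) < 1e-6)      # monotone regression

    def test_treated_output_grid_and_events(self, treated_result):
        res = treated_result
        assert res.time_hr[0] == 0.0 and res.time_hr[-1] == 504.0
        assert np.all(np.diff(res.time_hr) > 0)
        assert np.all(np.isfinite(res.states))
        # 21 boluses were administered (gut depot charged after each dose)
        assert res.scenario.regimen.n_doses == 21

    def test_output_grid_refinement_leaves_endpoint_unchanged(self, params, runtime):
        rp, x0 = runtime
        sc = Scenario("treated", DoseRegimen(40.0, 24.0, 4.0))
        a = simulate(sc, params, dt_out=4.0, runtime=rp, x0=x0)
        b = simulate(sc, params, dt_out=1.0, runtime=rp, x0=x0)
        assert a.observable_at("V_p", 96.0) == pytest.approx(
            b.observable_at("V_p", 96.0), rel=1e-6)

    def test_tolerance_tightening_changes_endpoint_below_half_percent(
            self, params, runtime, treated_result):
        rp, x0 = runtime
        sc = Scenario("treated", DoseRegimen(40.0, 24.0, 21.0))
        tight = simulate(sc, params, runtime=rp, x0=x0, rtol=1e-5, atol=1e-7)
        V_ref = treated_result.observable_at("V_p", 504.0)
        V_tight = tight.observable_at("V_p", 504.0)
        assert abs(V_tight - V_ref) / V_ref < 0.005

    def test_simulation_is_deterministic(self, params, runtime):
        rp, x0 = runtime
        sc = Scenario("treated", DoseRegimen(40.0, 24.0, 2.0))
        a = simulate(sc, params, runtime=rp, x0=x0)
        b = simulate(sc, params, runtime=rp, x0=x0)
        assert np.array_equal(a.states, b.states)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            Scenario("intact", regimen=DoseRegimen())
        with pytest.raises(ValueError):
            Scenario("banana")


class TestResultContainer:
    def test_dataframe_layout(self, treated_result):
        df = treated_result.to_dataframe()
        assert df.columns[0] == "time_hr"
        assert list(df.columns[1:1 + len(STATE_NAMES)]) == list(STATE_NAMES)
        assert all(c.startswith("obs_") for c in df.columns[1 + len(STATE_NAMES):])
        assert len(df.columns) == 1 + len(STATE_NAMES) + len(OBSERVABLE_NAMES)

    def test_observables_recomputable_from_states(self, treated_result):
        from redusim.model import observables

        res = treated_result
        i = len(res.time_hr) // 2
        fresh = np.fromiter(observables(res.states[i], res.runtime).values(), float)
        assert np.array_equal(fresh, res.observables[i])
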