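"""Assembly of the full derivative: steady-state residual, flux
antisymmetry, conservation, dissipativity, determinism and dimensional
homogeneity."""

import numpy as np
import pytest

from redusim import ModelParameters
from redusim.forcing import MG_TO_L
from redusim.model import (
    RuntimeParams,
    assemble_derivative,
    build_runtime,
    derivative_and_fluxes,
    observables,
    total_prostate_mass,
)
from redusim.state import S, state_from_dict, state_to_dict


def random_states(x0, rng, n=100):
    """Random positive states in a physiological envelope around x0."""
    base = np.maximum(np.abs(x0), 1e-3)
    return base * rng.uniform(0.2, 5.0, size=(n, len(x0)))


class TestSteadyState:
    def test_intact_residual_vanishes(self, runtime):
        rp, x0 = runtime
        r = assemble_derivative(0.0, x0, rp)
        scale = np.maximum(np.abs(x0), 1.0)
        assert np.max(np.abs(r) / scale) < 1e-8

    def test_derivative_is_pure(self, runtime, rng):
        rp, x0 = runtime
        y = x0 * rng.uniform(0.5, 2.0, size=len(x0))
        a = assemble_derivative(3.0, y, rp)
        b = assemble_derivative(3.0, y.copy(), rp)
        assert np.array_equal(a, b)

    def test_nonfinite_state_raises_naming_state(self, runtime):
        rp, x0 = runtime
        y = x0.copy()
        y[S.AT_BL] = np.nan
        with pytest.raises(FloatingPointError, match="AT_BL"):
            assemble_derivative(0.0, y, rp)


class TestFluxStructure:
    def test_blood_liver_transfer_is_antisymmetric(self, runtime, rng):
        """Switching the hepatic flow off changes dAT_l by +flux and dAT_bl
        by exactly -flux on arbitrary states: the transfer appears once with
        each sign and nowhere else."""
        rp, x0 = runtime
        p0 = rp.params.copy()
        p0.liver.Q_l = 1e-300
        rp_noflow = RuntimeParams(p0, rp.forced)
        for y in random_states(x0, rng, n=100):
            d1, fl = derivative_and_fluxes(0.0, y, rp)
            d0 = assemble_derivative(0.0, y, rp_noflow)
            flux_T = fl["flow_T_blood_to_liver"]
            flux_D = fl["flow_D_blood_to_liver"]
            assert d1[S.AT_L] - d0[S.AT_L] == pytest.approx(flux_T, rel=1e-9, abs=1e-12)
            assert d1[S.AT_BL] - d0[S.AT_BL] == pytest.approx(-flux_T, rel=1e-9, abs=1e-12)
            assert d1[S.AD_L] - d0[S.AD_L] == pytest.approx(flux_D, rel=1e-9, abs=1e-12)
            assert d1[S.AD_BL] - d0[S.AD_BL] == pytest.approx(-flux_D, rel=1e-9, abs=1e-12)

    def test_androgen_amount_balance_closes(self, runtime, rng):
        """Summing T-pool derivatives recovers exactly synthesis minus
        elimination/metabolism/binding terms: all transport cancels."""
        rp, x0 = runtime
        p = rp.params
        for y in random_states(x0, rng, n=50):
            dy, fl = derivative_and_fluxes(0.0, y, rp)
            total_T_dot = dy[[S.AT_L, S.AT_BL, S.AT_BD, S.AT_P]].sum()
            CT_l = y[S.AT_L] / (p.liver.V_l * p.liver.PT_l)
            expected = (
                fl["testes_T_production"]
                - fl["liver_mm_T_to_D"]
                - p.liver.k_lT * p.liver.V_l * CT_l
                - fl["enzyme_T_binding_nmol"]
                - fl["ar_T_binding_nmol"]
                + fl["ar_T_release_deg_nmol"]
            )
            assert total_T_dot == pytest.approx(expected, rel=1e-9, abs=1e-10)


class TestConservationAndDecay:
    def _conservative_runtime(self, runtime):
        """Copy of the runtime with every androgen source and sink disabled:
        flows and binding-free exchange only."""
        rp, x0 = runtime
        p = rp.params.copy()
        tiny = 1e-300
        p.liver.V_maxl = tiny
        p.liver.k_lT = tiny
        p.liver.k_lD = tiny
        p.enzyme.k1 = 1e6      # keep k2 = Km*k1 - kcat valid, then zero below
        fc = rp.forced.copy()
        fc.kT_prod = 0.0
        fc.CL_blD = 0.0
        rp2 = RuntimeParams(p, fc, testes_on=True)
        # zero the enzyme and receptor couplings directly (kcat exactly zero
        # keeps the Segal identity k2 = Km*k1 - kcat positive)
        p.enzyme.kcat = 0.0
        p.enzyme.k1 = tiny
        p.enzyme.k3 = tiny
        p.gene.konT = tiny
        p.gene.koffT = tiny
        p.gene.konD = tiny
        p.gene.koffD = tiny
        p.gene.kAR_deg = tiny
        return rp2, x0

    def test_total_androgen_conserved_without_sources_or_sinks(self, runtime):
        from scipy.integrate import solve_ivp
        from redusim.model import rhs

        rp2, x0 = self._conservative_runtime(runtime)
        sol = solve_ivp(rhs, (0, 200.0), x0, args=(rp2,), method="BDF",
                        rtol=1e-8, atol=1e-10)
        T_idx = [S.AT_L, S.AT_BL, S.AT_BD, S.AT_P]
        D_idx = [S.AD_L, S.AD_BL, S.AD_BD, S.AD_P]
        totT = sol.y[T_idx].sum(axis=0)
        totD = sol.y[D_idx].sum(axis=0)
        assert np.all(np.abs(totT - totT[0]) < 1e-6 * totT[0] + 1e-9)
        assert np.all(np.abs(totD - totD[0]) < 1e-6 * totD[0] + 1e-9)

    def test_pure_decay_when_synthesis_and_inputs_are_zeroed(self, runtime):
        """With testicular production, AR synthesis, enzyme synthesis and
        mass production all off, every pooled quantity decays."""
        from scipy.integrate import solve_ivp
        from redusim.model import rhs

        rp, x0 = runtime
        p = rp.params.copy()
        p.mass.k_cp1 = 1e-300
        p.mass.k_sec = 1e-300
        fc = rp.forced.copy()
        fc.kT_prod = 0.0
        fc.kAR_syn = 0.0
        fc.K_occ = {g: 1e300 for g in fc.K_occ}     # occupancies -> 0: no E_syn
        rp2 = RuntimeParams(p, fc)
        sol = solve_ivp(rhs, (0, 100.0), x0, args=(rp2,), method="BDF",
                        rtol=1e-8, atol=1e-10, t_eval=np.linspace(0, 100, 21))
        V_pL = np.array([total_prostate_mass(y, p) for y in sol.y.T]) * MG_TO_L
        pools = {
            "T": sol.y[[S.AT_L, S.AT_BL, S.AT_BD, S.AT_P]].sum(axis=0)
                 + (sol.y[S.ET] + sol.y[S.ART]) * V_pL,
            "AR": (sol.y[S.AR] + sol.y[S.ART] + sol.y[S.ARD]) * V_pL,
            "enzyme": (sol.y[S.E] + sol.y[S.ET]) * V_pL,
            "mass": sol.y[S.VPC_1] + sol.y[S.VPL_1],
        }
        for name, tot in pools.items():
            assert np.all(np.diff(tot) < 1e-9), name
            assert tot[-1] < tot[0]


class TestObservablesAndLayout:
    def test_observables_recomputable_and_consistent(self, runtime):
        rp, x0 = runtime
        obs = observables(x0, rp)
        assert obs["V_p"] == pytest.approx(457.0)
        assert obs["total_mass"] == obs["V_p"]
        assert obs["CT_pf"] == pytest.approx(rp.forced.CT_pf0, rel=1e-12)
        assert obs["Q_p"] > 0
        for g in ("DNAo_cp", "DNAo_cd", "DNAo_sec", "DNAo_5aR2"):
            assert obs[g] == pytest.approx(0.95, rel=1e-9)

    def test_state_serialization_roundtrip(self, runtime):
        rp, x0 = runtime
        assert np.array_equal(state_from_dict(state_to_dict(x0)), x0)
        with pytest.raises(KeyError):
            state_from_dict({"bogus": 1.0})

    def test_total_prostate_mass_decomposition(self, runtime):
        rp, x0 = runtime
        p = rp.params
        assert total_prostate_mass(x0, p) == pytest.approx(457.0)
        y = x0.copy()
        y[S.VPC_1] = 0.0
        y[S.VPL_1] = 0.0
        assert total_prostate_mass(y, p) == pytest.approx(36.2)
        y[S.VPC_1] = 10.0
        assert total_prostate_mass(y, p) == pytest.approx(46.2)


class TestDimensionalHomogeneity:
    def test_amount_derivatives_scale_with_system_size(self, runtime, rng):
        """Scaling every volume, flow, capacity and amount by the same
        factor scales amount/mass derivatives by that factor and leaves
        concentration derivatives untouched: the unit audit in one law."""
        lam = 3.0
        rp, x0 = runtime
        p2 = rp.params.copy()
        for sec, name in [
            ("liver", "Q_l"), ("liver", "V_maxl"), ("liver", "V_l"),
            ("axis", "V_bl"), ("axis", "V_bd"), ("axis", "Q_bd"),
            ("pk", "Vc"),
            ("mass", "k_cp1"), ("mass", "k_sec"), ("mass", "VPC_1b"),
            ("mass", "VPC_2"), ("mass", "VPL_2"), ("mass", "V_p_total0"),
        ]:
            obj = getattr(p2, sec)
            setattr(obj, name, getattr(obj, name) * lam)
        fc2 = rp.forced.copy()
        fc2.Qp0 *= lam
        fc2.PS_pD0 *= lam
        fc2.kT_prod *= lam
        fc2.CL_blD *= lam
        fc2.V_p0 *= lam
        fc2.kAR_syn = rp.forced.kAR_syn     # nM/hr: intensive, unchanged
        rp2 = RuntimeParams(p2, fc2)

        amount_idx = [S.A1_F, S.A2_F, S.A3_F, S.AT_L, S.AD_L, S.AT_BL, S.AD_BL,
                      S.AT_BD, S.AD_BD, S.AT_P, S.AD_P, S.VPC_1, S.VPL_1]
        conc_idx = [S.LH, S.E, S.ET, S.EF, S.EFSTAR, S.AR, S.ART, S.ARD]
        for y in random_states(x0, rng, n=20):
            y2 = y.copy()
            for i in amount_idx:
                y2[i] = y[i] * lam
            d1 = assemble_derivative(0.0, y, rp)
            d2 = assemble_derivative(0.0, y2, rp2)
            assert np.allclose(d2[amount_idx], lam * d1[amount_idx], rtol=1e-9)
            assert np.allclose(d2[conc_idx], d1[conc_idx], rtol=1e-9)
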