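# Methods

## Scope and state

`redusim` simulates androgen regulation of the adult male rat ventral
prostate under three conditions: intact, castrated, and orally dosed with
the 5α-reductase inhibitor finasteride. The state vector (21 entries,
frozen in `redusim.state.S`) carries finasteride amounts in a
gut/central/peripheral PK chain (nmol), T and DHT amounts in liver,
blood, a lumped body compartment and the prostate (nmol), normalized LH,
four prostatic 5aR2 species and three AR species (nM), and the two
androgen-sensitive prostate mass compartments (mg). Units are hours,
nmol, nM, mg and litres throughout; 1 mg of prostate tissue is treated
as 1 µL.

## Organ modules

**Finasteride PK.** First-order absorption (ka) into a central
compartment cleared at k10, exchanging with a small peripheral pool
(k12, k21). Only unbound drug, `F = fu·A2/Vc` with fu = 0.10, acts on
the enzymes; free drug is assumed in instantaneous equilibrium with
well-perfused tissue, so the same `F` inhibits liver and prostate. Net
binding to prostatic 5aR2, `(k3·F·E − k4·EF)·V_p`, is an explicit sink
on the central compartment, so drug sequestered in EF/EF\* is accounted
mass-balance-exactly.

**Liver.** 5aR1 converts T to DHT with competitive, reversible
inhibition: `v = V_maxl·CT_l/(K_m5a·(1 + F/Ki_5aR1) + CT_l)`. 5aR1 is
treated as liver-exclusive and its activity as constant across
scenarios (no androgen regulation). The printed nonspecific elimination
constants k_lT = 87.9 hr⁻¹ and k_lD = 77.2 hr⁻¹ are dimensionally
implausible as amount rate constants and are applied as clearance
coefficients `k·V_l·C` (≈0.4 L/hr at the default V_l), consistent with
the 1.06 L/hr hepatic flow.

**Prostatic 5aR2.** Mass-action kinetics with substrate binding
(k1 = 500 hr⁻¹nM⁻¹), the Segal identity `k2 = Km·k1 − kcat = 30 hr⁻¹`
(Km = 0.6 nM, kcat = 270 hr⁻¹), competitive inhibitor binding
(k3 = 1000 hr⁻¹nM⁻¹, `k4 = Ki·k3 = 500 hr⁻¹`, Ki = 0.5 nM) and slow
isomerization of EF to the quasi-permanently inhibited EF\*
(k5 = 3.96 hr⁻¹, k6 = 0 exactly). Synthesis is driven by occupancy of
the 5aR2 gene, `E_syn = k_dg·E₀·(DNAo/DNAo₀)` with E₀ = 19 nM free
enzyme, and degradation k_dg = 0.016 hr⁻¹ applies to E, EF and EF\* but
*not* to the catalytic complex ET. That asymmetry is a deliberate
choice: it makes the intact partition (19 nM free + 1 nM bound = 20 nM
total, synthesis = k_dg·19) exactly self-consistent, and it lets
permanently inhibited enzyme clear after washout with mean lifetime
1/k_dg ≈ 62.5 h, which is what makes DHT rebound far slower than drug
clearance. The 20 nM total pool matches the estimate from 5aR2 being
~0.001% of 53 mg/g prostatic protein at 28,772 Da (18.4 nM, rounded up).

**AR and gene occupancy.** AR, AR:T and AR:DHT are dynamic with shared
first-order turnover (half-life 3 h, a literature-anchored choice);
ligand carried by degraded complexes returns to the free androgen pool
(mass conservation preferred over tacit elimination). Dimerization and
DNA binding are algebraic quasi-equilibria: `TT = k_dim·ART²`,
`TD = 2k_dim·ART·ARD`, `DD = k_dim·ARD²`, and each of the four regulated
genes (proliferation, anti-apoptosis, fluid production, 5aR2) sees the
potency-weighted pool `P = DD + w·TD + TT/k_DNAoffTT` through a
hyperbola `DNAo = P/(K_occ + P)`. k_DNAoffTT = 1.6 divides TT potency
(TT dimers are weaker transactivators); w defaults to the geometric mean
1/√1.6. DNA sites are not modeled explicitly: dimers exceed sites
roughly 40-fold, and the test suite verifies against a brute-force
finite-site equilibrium solver that site depletion would change
occupancy by <5% in that regime.

**Prostate mass.** `dVPC₁/dt = k_cp1·DNAo_cp − k_cd1·(1 − DNAo_cd)·VPC₁`
(growth saturates through occupancy, not through a capacity term — a
capacity factor would prevent regrowth after drug withdrawal) and
`dVPL₁/dt = k_sec·DNAo_sec − k_lum·VPL₁`, plus constant basal
compartments VPC₂ = 18 and VPL₂ = 18.2 mg. The death and lumen-clearance
constants are forced to zero the derivatives at the intact anchors.
k_sec = 5 mg/hr makes the forced lumen clearance (k_lum ≈ 0.021 hr⁻¹)
regress the lumen on the same multi-day timescale as the cellular
compartment, so castration reaches the 36.2 mg basal mass within the
21-day study window. Prostatic blood flow and the DHT exchange
coefficient scale with current mass.

**Endocrine axis.** Blood exchanges T and DHT flow-limited with liver
and the lumped body (brain included), and with the prostate: T uptake is
flow-limited (the intact gland extracts >99% of delivered T into DHT
production), while DHT *efflux is diffusion-limited*, with a forced
transfer coefficient PS_pD ≈ 0.2·Q_p. This asymmetry is what lets free
prostatic DHT (30 nM anchor) sit two orders of magnitude above blood DHT
(0.3 nM): with purely flow-limited exchange, the intact trans-prostatic
DHT gradient could never exceed the blood T level (~6 nM), the gene
signal would have to be carried by concentrations comparable to treated
prostatic T, and neither the observed depth of regression nor the
dosing-frequency behavior can then coexist with the sensitivity
structure. LH follows
`dLH/dt = kLH_prod/(1 + ((CT_bl + CD_bl)/K_inh)²) − kLH_deg·LH` and
drives testicular T production; the Hill exponent 2 with kLH_deg =
1.4 hr⁻¹ gives the damped post-dose oscillations of blood T. An
additional blood-side DHT clearance (forced) folds extra-hepatic
elimination into one term. Castration zeroes testicular production.

## Steady-state forcing

The intact animal is an exact equilibrium by construction
(`redusim.forcing`): the enzyme partition pins free prostatic T at
`Km·ET₀/E₀ = 0.0316 nM`; the liver balance is solved by a scalar root
find; prostate flow, DHT transfer, testicular production, blood DHT
clearance, LH production, AR synthesis, the four occupancy
half-saturation constants and the mass death/clearance constants each
close one balance at the anchors. The assembled state has residual at
machine precision; a damped Newton polish exists as a fallback but is
not normally exercised.

## Calibrated constants

Constants inherited from the base castration model are not printed in
the available sources; they are calibrated once, anchored to printed
steady states and outcomes, and shipped as the package defaults:

| constant | value | anchored to |
|---|---|---|
| blood T / DHT anchors | 6 / 0.3 nM | normal adult rat ranges; DHT ≪ T |
| free prostatic DHT anchor | 30 nM | reported prostatic DHT ≫ blood DHT |
| AR effective Kd for DHT / T | 60 / 122 nM | treated-arm regression depth and the TT-vs-DD signal balance |
| AR turnover | t½ = 3 h | literature value |
| V_l (liver distribution volume) | 0.005 L | blood-T sensitivity to hepatic Km |
| PK: ka, k10 | 1.0, 0.45 hr⁻¹ | fast rat clearance (α t½ ≈ 1.6 h); trough free drug ~1–3 nM |
| PK: k12, k21 | 0.004, 0.02 hr⁻¹ | a small (~1% of dose) slow tissue pool that sustains sub-nM–nM free drug through long inter-dose gaps |
| K_inh, kLH_deg, Hill n | 6.3 nM, 1.4 hr⁻¹, 2 | intact LH level, damped T oscillations |

Three of these deserve comment. The fast α-phase is required by the
sensitivity structure: the day-21 coefficients of prostatic DHT with
respect to kcat, Km, k5 and Ki_5aR2 are only large if a meaningful share
of residual prostatic DHT is *locally produced* by newly synthesized
enzyme surviving near the dosing trough, which needs free drug to fall
to the low-nM range before the next dose. The slow tail is required by
the dosing-frequency behavior: 36-hour dosing regresses the prostate
nearly as much as daily dosing only if enzyme resynthesized during the
long gap is still captured, which a ~35 h-half-life deep pool holding
~1 nM free drug accomplishes while still clearing >98% of drug within a
day of the last dose. The moderate effective AR affinity for T (about
half the DHT potency per dimer after the TT weighting) makes elevated
treated T maintain roughly a quarter of the gland — enough that T alone
cannot sustain normal size, yet enough to make twice-daily dosing
(which maximizes the T compensation) slightly *less* effective than
daily dosing.

With these defaults the model yields a 75.7% mass decrease after
21 days of daily 40 mg/kg finasteride, day-21 control coefficients of
free prostatic DHT of +0.75 (kcat), −0.74 (Km), +0.75 (k_dg),
−0.73 (k5), +0.74 (Ki_5aR2), near-zero sensitivity to k1, k3 and k6,
and day-21 masses ordered V(24 h) < V(12 h) with V(36 h) within 3% of
V(24 h) — all recomputed by the test suite and `scripts/acceptance.py`,
never hard-coded.

## Synthetic study data

`generate_fixture` emulates the calibration study design: three arms
(intact, castrated, treated 40 mg/kg once daily), sampled at days 0, 4,
9, 14 and 21, measuring free prostatic T and DHT and total prostate
mass, with multiplicative lognormal noise of configurable CV (default
5%, mean-preserving) and seeded reproducibility. It emulates the
*design*, not the animals: values come from the model itself, so
calibration tests demonstrate that the estimation machinery recovers
known parameters from data of that shape and noise level (k_dg to within
a few percent from 20-replicate fixtures; the k_DNAoffTT potency exactly
on noise-free treated masses) — they cannot show that the model fits
real prostates, inter-animal variability, or measurement artifacts such
as tissue-extraction bias. The Km/k_dg trade-off reported by
`kdg_km_tradeoff` reproduces the known sloppiness: doubling Km is
absorbed almost exactly by doubling k_dg.

## Numerics

- Integration: SciPy `solve_ivp` BDF, rtol 1e-4 / atol 1e-6 (defaults,
  configurable). Tightening both 10× moves the day-21 treated mass by
  <0.5% (tested).
- Dosing: integrator restart at each bolus (gut depot incremented by
  `dose·BW/MW·10⁶` nmol); trajectory values at an event time are
  pre-dose, so "day 21" of a daily regimen is sampled the instant before
  the 22nd dose would occur.
- Negativity: states are never clipped; any output excursion below
  −(100·atol + 10⁻⁹·scale) aborts with the offending state named.
- Sensitivity: forward difference with Δp = +1%, both runs from the same
  baseline steady state. The derived identities k2 and k4 are recomputed
  from the perturbed primaries (so Km and Ki_5aR2 act through them), but
  steady-state forcings are *not* re-solved — the perturbation probes
  the calibrated model, it does not re-calibrate it.
- Calibration: unweighted least squares on log-scale residuals,
  parameters on a log scale; every candidate re-runs the steady-state
  forcing so all explored models honor the intact anchors.
- Local stability: a +1% whole-state perturbation decays back to the
  intact state, but the slowest mode — the androgen-sensitive cellular
  mass, whose linearized death rate is k_cd1·(1−0.95) ≈ 0.0025 hr⁻¹ by
  construction of the forcing — has a ~17-day half-time, so the
  verification window is 1500 h.

## Known limitations

- AR levels are not androgen-regulated, and chaperone/cofactor biology
  is absent; the dimer/occupancy layer is a deliberately minimal
  quasi-equilibrium summary.
- Regrowth after androgen restoration needs proliferation mechanisms
  beyond the occupancy-driven growth term and is out of scope.
- Only finasteride is parameterized; the config format accepts other
  compounds (e.g. a dual inhibitor) but no such parameter set ships.
- The unprinted-constant calibration is not unique: the Km/k_dg pair is
  the documented example, and the PK deep pool trades off against the
  AR affinity ratio within limits. The shipped defaults are one
  consistent point estimate, every element of which is exposed in the
  config.
- Castration is modeled as an instantaneous loss of testicular
  production; surgical stress and adrenal androgens are ignored.
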