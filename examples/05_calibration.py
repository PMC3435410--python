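"""Synthetic study fixture and parameter estimation.

Generates a three-arm study (intact, castrated, 40 mg/kg once daily)
sampled at days 0, 4, 9, 14 and 21 with 5% multiplicative noise, then
re-estimates the 5aR2 degradation rate from the treated-arm prostatic DHT
time course, starting from a deliberately wrong value.  Finally a short
scan illustrates the Km/k_dg sloppiness: similar fits are obtained at a
different Km by compensating with k_dg.
"""

from redusim import ModelParameters, calibrate, generate_fixture
from redusim.calibrate import kdg_km_tradeoff

fixture = generate_fixture(noise_cv=0.05, seed=42, n_replicates=4)
print(f"fixture: {len(fixture)} measurements across "
      f"{fixture['arm'].nunique()} arms")

start = ModelParameters()
start.enzyme.k_dg = 0.024          # 50% above the true value of 0.016
fit = calibrate(fixture, ["k_dg"], params=start)
k = fit.fitted["k_dg"]
print(f"recovered k_dg = {k:.5f} hr^-1 (truth 0.016; "
      f"error {100 * abs(k - 0.016) / 0.016:.1f}%), se = {fit.se['k_dg']:.2g}")

print()
print("Km / k_dg trade-off (refit k_dg at fixed Km):")
scan = kdg_km_tradeoff(fixture, [0.6, 1.2], params=start)
for row in scan.itertuples(index=False):
    print(f"  Km = {row.Km:4.1f} nM -> k_dg = {row.k_dg_fitted:.5f} hr^-1, "
          f"residual norm {row.residual_norm:.3f}")
print("A doubled Km is absorbed by a faster degradation rate with only a")
print("modest change in fit quality, so Km is fixed to its measured value")
print("and only k_dg is treated as free.")
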