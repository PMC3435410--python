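"""Construct the intact adult male rat steady state and inspect its anchors.

The steady state is built algebraically: each unprinted constant is forced
so the corresponding balance equation vanishes exactly at the anchor
values (free 5aR2, 5aR2:T, occupancies, blood androgens, prostate mass).
"""

from redusim import initialize_steady_state
from redusim.model import observables
from redusim.state import S

rp, x0 = initialize_steady_state()
obs = observables(x0, rp)

print("Intact steady state (adult male rat):")
print(f"  free prostatic 5aR2        : {x0[S.E]:.2f} nM")
print(f"  5aR2:T complex             : {x0[S.ET]:.2f} nM")
print(f"  total 5aR2 pool            : {x0[S.E] + x0[S.ET]:.2f} nM")
print(f"  free prostatic T           : {obs['CT_pf']:.4f} nM")
print(f"  free prostatic DHT         : {obs['CD_pf']:.1f} nM")
print(f"  blood T / DHT              : {obs['CT_bl']:.1f} / {obs['CD_bl']:.2f} nM")
print(f"  total prostate mass        : {obs['V_p']:.1f} mg")
print(f"  gene occupancies (all)     : {obs['DNAo_cd']:.2f}")
print()
print("The enzyme partition (19 nM free vs 1 nM substrate-bound) pins free")
print("prostatic T at Km/19; prostatic DHT sits two orders of magnitude")
print("above blood DHT because it is produced locally and leaves the gland")
print("through a diffusion-limited exchange.")
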