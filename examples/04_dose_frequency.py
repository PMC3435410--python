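"""Dosing-regimen comparison: why once-daily can beat twice-daily.

At a fixed 40 mg/kg per administration, a 12-hour schedule keeps DHT
suppressed continuously, but the sustained DHT pressure drives a stronger
testosterone compensation (through LH feedback and reduced prostatic T
consumption), and that extra T signal partially maintains the gland.  The
once-daily schedule lets a little DHT production return at each trough
yet carries less total androgen-receptor signal on average, and a 36-hour
schedule comes close to it because the slow drug tail and the permanently
inactivated enzyme pool keep DHT production down between doses.
"""

import numpy as np

from redusim import DoseRegimen, ModelParameters, Scenario, simulate
from redusim.analysis import dose_frequency_surface, normalized_signal

params = ModelParameters()
print("Day-21 prostate mass at 40 mg/kg per dose:")
for tau in (12.0, 24.0, 36.0):
    res = simulate(Scenario("treated", DoseRegimen(40.0, tau, 21.0)),
                   params, t_end_hr=504.0, dt_out=2.0)
    sig, mean = normalized_signal(res.observable("CT_pf"), res.observable("CD_pf"),
                                  params, time_hr=res.time_hr,
                                  window_hr=(408.0, 504.0))
    print(f"  every {tau:4.0f} h: V = {res.observable_at('V_p', 504.0):6.1f} mg; "
          f"mean normalized T+DHT signal (last 4 days) = {mean:.3f}")

print()
print("Small dose x interval surface (end-of-treatment mass, mg):")
grid = dose_frequency_surface(params, doses=[0.1, 4.0, 160.0],
                              intervals=[12.0, 24.0, 48.0])
print("        " + "".join(f"{i:>9.0f}h" for i in grid.intervals))
for d, row in zip(grid.doses, grid.V_end):
    print(f"{d:7.1f} " + "".join(f"{v:>10.1f}" for v in row))
print()
print("Mass falls with dose at every interval; at high dose the interval")
print("matters little because the slow drug tail spans even 48-hour gaps.")
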