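"""Seasonal contrast in the fate of dissolved seep methane.

Runs the full chain (synthetic 65 m station-year -> bubble deposition
-> diffusion-reaction transport) for releases starting in January and
in July, at a 50-day biodegradation half-life.  In winter the column
is well mixed and most of the dissolved methane escapes to the
atmosphere; in summer the pycnocline traps it below the mixed layer,
where biodegradation wins.
"""

import numpy as np

from seepfate import (AmbientProfile, halflife_to_rate, integrate_bubble,
                      make_scenario, run_until_depleted, station_preset,
                      ventilation_rate)

scenario = make_scenario(station_preset(65), seed=1)
profile = AmbientProfile.from_scenario(scenario, day=0.0)
deposition = integrate_bubble(profile, 65.0,
                              cell_edges=scenario.cell_edges).deposition
k1 = float(halflife_to_rate(50.0))

for label, start in (("January", 0.0), ("July", 181.0)):
    mb = run_until_depleted(deposition, scenario, k1, start_day=start)
    term = mb.terminal
    v = ventilation_rate(mb)
    print(f"{label} release (t1/2 = 50 d):")
    print(f"  ventilated {100 * term['ventilated']:.1f}%  "
          f"biodegraded {100 * term['biodegraded']:.1f}%  "
          f"direct bubble {100 * term['bubble']:.2f}%")
    print(f"  ventilation rate over the first month: "
          f"{np.nanmedian(v.v[2:30]):.4f} 1/d vs k1 = {k1:.4f} 1/d")
print("The v:k1 ratio sets the branching between escape to the atmosphere")
print("and biodegradation; the summer pycnocline pushes v far below k1.")
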