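"""Epithelial delivery of insulin + C10 under segmentation.

Simulates a short (six-period) baseline segmentation case and prints the
near-wall mole percentages, escape fraction, and surface-concentration
summaries that the full study tracks over thirty periods.
"""

import numpy as np

from lumenflow import MotilityCase, run_case

case = MotilityCase(
    motility="segmentation",
    intensity="moderate",
    fluid_id="nutridrink_default",
    pocket_volume=2.0,
    occlusion_ratio=0.3,
    release_position="most_occluded",
)
res = run_case(case, "coarse", n_periods=6)
m = res.metrics
t = np.array(m.times)

print(f"case: {case.label()}")
print(f"Reynolds {m.reynolds:.1f}; Peclet insulin {m.peclet['insulin']:.2e}")
for p in (2, 4, 6):
    i = np.searchsorted(t, p * res.geom.period) - 1
    print(
        f"after {p} periods: {m.near_wall_pct['insulin']['D15'][i]:5.1f}% of insulin "
        f"within D/15 of the wall, {m.near_wall_pct['insulin']['D30'][i]:5.1f}% within D/30, "
        f"{m.escape_pct['insulin'][i]:4.1f}% escaped the release pocket"
    )
for sp in ("insulin", "C10"):
    pk = m.peaks[sp]
    onset = f"{m.onset[sp]:.0f} s" if m.onset[sp] is not None else "not yet"
    print(
        f"{sp:8s}: max wall c/ci so far {pk.value:.4f} at t={pk.t:.0f} s, "
        f"z={pk.z:.2f} cm; detection onset (c/ci > 0.001): {onset}"
    )
print("(the near-wall percentages keep climbing for several more periods;")
print(" the thirty-period study tracks the full rise and decay)")
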