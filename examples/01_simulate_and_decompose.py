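"""Simulate the tri-tissue leukemia model and decompose the spleen dynamics.

Builds the calibrated default scenario (PB-coupled mobility), integrates it
over the 21-day course, prints the cell counts at the measurement days, and
projects the spleen normal-cell dynamics onto its acting mechanisms
(proliferation, death, import, export).
"""

import numpy as np

from hemakin import decompose, observe, rank_factors, simulate
from hemakin.scenarios import default_scenario
from hemakin.simulate import OBS_DAYS

sc = default_scenario()
traj = simulate(sc.spec, sc.params, sc.x0, span=(0, 21), obs_days=OBS_DAYS)
obs = observe(traj, OBS_DAYS)

print("Cell counts at the measurement days (cells):")
print(f"{'series':>14s}" + "".join(f"{d:>11.0f}" for d in OBS_DAYS))
for key in sc.series_keys:
    print(f"{key[0] + ' ' + key[1]:>14s}" + "".join(f"{v:>11.3g}" for v in obs[key]))
print("Leukemic cells expand in every tissue; PB normal cells rise after day 7,")
print("the spleen peaks mid-course and falls, the marrow empties to a day-21 minimum.\n")

dec = decompose(sc.spec, sc.params, traj)
print("Spleen normal-cell mechanism rates (cells/day) at days 7/12/21:")
frame = dec.signed_frame(("SP", "normal"))
for day in (7.0, 12.0, 21.0):
    row = frame.loc[np.isclose(frame.index, day)].iloc[0]
    terms = "  ".join(f"{proc.split('.')[-1]}={v:+.0f}" for proc, v in row.items())
    print(f"  day {day:4.0f}: {terms}  (net {row.sum():+.0f})")
print("Early on, import from the blood outweighs export and death (the rise);")
print("late, the import flux collapses with the PB pool and the net turns negative.\n")

rk = rank_factors(dec, ("SP", "normal"))
print("Factor ranking for the spleen (mean |rate| over days 0-21):")
print(rk.table.to_string(index=False))
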