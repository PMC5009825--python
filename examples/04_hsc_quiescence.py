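"""HSC suppression: differentiation blockade and G0 re-entry.

Runs the two nested sub-models on their synthetic scenarios: (1) the
HSC/HPC model, reporting the per-day-interval flux of HSCs differentiating
into HPCs (the blockade: the flux nearly vanishes by day 21); (2) the
quiescence model, reporting the G0 fraction and comparing the re-entry
mechanism against selective exhaustion of cycling cells on the
quiescent-HSC count series.
"""

import numpy as np

from hemakin.analysis import day_intervals, interval_flux, run_selection_experiment
from hemakin.fitting import GAConfig, fit_stagewise
from hemakin import presets
from hemakin.scenarios import (
    generate, hsc_hpc_scenario, leukemic_bm_forcing, quiescence_scenario,
    scenario_trajectory, scenario_truth,
)

forcing = leukemic_bm_forcing()

# --- differentiation blockade
sc = hsc_hpc_scenario()
traj = scenario_trajectory(sc)
flux = interval_flux(sc.spec, sc.params, traj, "BM.HSC.HSC_to_HPC",
                     day_intervals(21), forcing=forcing).flux
print("HSC -> HPC differentiation flux per day interval (cells):")
for i in range(0, 21, 3):
    print(f"  days {i:2d}-{i + 3:2d}: " +
          " ".join(f"{v:8.1f}" for v in flux[i:i + 3]))
print(f"final interval / maximum interval = {flux[-1] / flux.max():.4f}")
print("Fewer and fewer HSCs differentiate as leukemia advances; the flux has")
print("nearly vanished by day 21 — a differentiation blockade that starves the")
print("progenitor pool.\n")

# --- quiescence and G0 re-entry
truth = scenario_truth(quiescence_scenario("on", cv=0.0))
frac = 100 * truth[("BM", "HSC_G0")] / truth[("BM", "HSC")]
days = [0, 7, 10, 12, 14, 21]
print("G0 fraction of HSCs (%):",
      "  ".join(f"d{d}:{f:.1f}" for d, f in zip(days, frac)))
print("40 % of HSCs are quiescent at baseline; >92 % from day 14 on.\n")

data = generate(quiescence_scenario("on", cv=0.15), seed=0)
ga = GAConfig(population=24, generations=25, refine_starts=2)
fns = {}
for label, mode in (("reentry", "on"), ("exhaustion", "off")):
    spec = presets.g0_spec(mode)
    tmpl = presets.g0_template(spec)
    stages = presets.g0_stages(spec)

    def fn(seed, spec=spec, tmpl=tmpl, stages=stages):
        return fit_stagewise(spec, data, stages, ga, template=tmpl,
                             forcing=forcing, seed=seed)

    fns[label] = fn

exp = run_selection_experiment(data, fns, n_restarts=4, seed0=0,
                               contested_series=[("BM", "HSC_G0")], alpha=0.1)
res = exp.tests[("reentry", "exhaustion")]
print("Quiescent-HSC series fit errors:")
for label, errs in exp.errors.items():
    print(f"  {label:11s} mean {errs.mean():6.3f}")
print(f"one-tail Welch p = {res.p:.2e}, winner = {res.winner}")
print("Only the re-entry mechanism can raise the absolute quiescent count —")
print("killing cycling cells raises the fraction but never the count.")
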