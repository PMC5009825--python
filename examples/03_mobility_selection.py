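"""Model selection: is cell mobility between tissues needed?

Fits three variants of the tissue model — migration coupled to the PB
circulation, migration as constants unrelated to PB, and no migration — to
the same synthetic dataset (generated under PB-coupled mobility), with a
small restart ensemble per variant, and compares the spleen-series fit
errors with one-tailed Welch t-tests.  A short demonstration run: the study
configuration uses 10 restarts and larger GA budgets (see tests and
scripts/acceptance.py).
"""

from hemakin.analysis import run_selection_experiment
from hemakin.fitting import GAConfig, fit_stagewise
from hemakin import presets
from hemakin.scenarios import default_scenario, generate

data = generate(default_scenario(cv=0.15), seed=0)
ga = [GAConfig(population=16, generations=15, refine_starts=2),
      GAConfig(population=24, generations=20, refine_starts=2)]

variants = {}
for mode in ("pb_coupled", "constant", "zero"):
    spec = presets.tissue_spec(mode)
    tmpl = presets.tissue_template(spec)
    stages = presets.tissue_stages(spec)

    def fit_fn(seed, spec=spec, tmpl=tmpl, stages=stages):
        return fit_stagewise(spec, data, stages, ga, template=tmpl, seed=seed)

    variants[mode] = fit_fn

exp = run_selection_experiment(
    data, variants, n_restarts=4, seed0=0,
    contested_series=[("SP", "leukemic"), ("SP", "normal")], alpha=0.005,
)

print("Per-restart spleen-series errors (sum of d/s over the two SP series):")
for label, errs in exp.errors.items():
    print(f"  {label:11s} mean {errs.mean():6.3f}   restarts {[round(float(e), 3) for e in errs]}")
print()
for (a, b), r in exp.tests.items():
    print(f"  {a} vs {b}: t = {r.t:7.2f}, one-tail p = {r.p:.2e}, winner = {r.winner}")
print("\nThe PB-coupled model explains the spleen rise-and-fall that the plain")
print("variants cannot: ignoring circulation (zero) leaves the spleen monotone,")
print("and a constant migration term cannot time the fall correctly.")
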