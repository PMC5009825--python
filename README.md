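# hemakin

Compartmental ODE modeling of **tri-tissue hematopoiesis under acute
myeloid leukemia (AML)** — a digital counterpart of a non-irradiated mouse
leukemia experiment, for systems biologists who want to reconstruct how
*normal* blood cells respond to a growing leukemic burden from cell-count
kinetics alone.

The model treats peripheral blood (PB), spleen (SP) and bone marrow (BM) as
three connected compartments, each holding a leukemic and a normal
hematopoietic population.  Every population count $X$ evolves as

$$\frac{dX}{dt} = f_{\mathrm{Prolif}} - f_{\mathrm{Death}} - f_{\mathrm{Export}} + f_{\mathrm{Import}}$$

where each $f_i$ is an elementary kinetic law (zero/first order,
exponential-saturating, Michaelis–Menten, Hill) times a Hill-form leukemic
modifier $K(L)$ — suppressive $K = 1/(1+(L/\theta_L)^{h})$ or stimulative
$K = 1 + \beta L^{h}/(\theta_L^{h}+L^{h})$ — with $K(0)=1$, so purging the
couplings to zero recovers the disease-free control model exactly.  Nested
sub-models resolve the BM primitive cells (HSC/HPC) and the
quiescent/active HSC split (G0 level), forced by the fitted leukemic-BM
trajectory.

On top of the model the package provides:

* **structure enumeration** — a finite pool of candidate models from
  per-process kinetic-form choices, reducing structure uncertainty to
  ordinary parameter estimation;
* **parameter estimation** — a seeded genetic algorithm with trust-region
  least-squares refinement against the $d \le s$ fitness criterion
  ($d$ = RMS deviation of simulated from observed means, $s$ = experimental
  sample SD);
* **parametric analysis** — exact decomposition of fitted dynamics onto
  mechanism rates, per-day-interval fluxes (e.g. HSC→HPC differentiation),
  and factor ranking;
* **model selection** — multi-restart error ensembles compared by
  one-tailed Welch t-tests (cell mobility: PB-coupled vs constant vs none;
  HSC quiescence: G0 re-entry vs selective exhaustion);
* **a synthetic-data generator** — calibrated ground-truth scenarios
  emulating the experimental kinetics (measurement days 0/7/10/12/14/21,
  3 replicates, lognormal noise at CV 15 %), so the whole pipeline is
  testable without any external data.

## A worked example

```python
from hemakin.fitting import GAConfig, fit_stagewise
from hemakin import presets
from hemakin.scenarios import default_scenario, generate

data = generate(default_scenario(cv=0.15, n_replicates=3), seed=1)
spec = presets.tissue_spec("pb_coupled")
ga = [GAConfig(population=32, generations=40, refine_starts=2),
      GAConfig(population=64, generations=70, refine_starts=4)]
res = fit_stagewise(spec, data, presets.tissue_stages(spec), ga,
                    template=presets.tissue_template(spec), seed=1)
print(res.table().to_string(index=False))
```

prints the per-series fitness table of the staged fit (leukemic subsystem
first, then the normal cells conditional on it):

```
tissue population           d            s  fit
    PB   leukemic  909.923572 14581.417323 True
    SP   leukemic 5246.297555 74768.241309 True
    BM   leukemic 7676.262162 64915.630741 True
    PB     normal  606.966501  1696.071786 True
    SP     normal 2147.999948  6708.303609 True
    BM     normal  922.700597  6934.950859 True
```

Every series satisfies $d \le s$: the fitted curves lie within the
experimental scatter of the synthetic measurements.  The fitted BM leukemic
growth constant comes back as 0.709/day against a generating value of
0.700/day — the one rate constant that is practically identifiable at this
noise level (see `docs/methods.md` on identifiability).

The `examples/` directory holds one short narrative script per capability:
simulation + mechanism decomposition, fitting, the cell-mobility model
selection, and the HSC differentiation-blockade / G0 re-entry analyses.
A thin CLI mirrors the pipeline stages
(`hemakin synth | simulate | fit | decompose | flux | select`).

## Layout

| path | contents |
|---|---|
| `src/hemakin/rates.py` | elementary rate laws, leukemic modifier |
| `src/hemakin/model.py` | model spec, RHS compilation, enumeration, control reduction, homeostatic closure |
| `src/hemakin/simulate.py` | stiff integration, observation, forcing |
| `src/hemakin/fitting.py` | d ≤ s criterion, GA + refinement, restarts, identifiability forecast |
| `src/hemakin/analysis.py` | decomposition, interval fluxes, factor ranking, Welch selection |
| `src/hemakin/scenarios.py` | calibrated synthetic study conditions |
| `src/hemakin/presets.py` | canonical model structures, truths, bounds, fitting stages |
| `src/hemakin/io.py`, `cli.py` | CSV/JSON round-trips, thin CLI |
| `docs/methods.md` | model assumptions, numerics, calibration, limitations |
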