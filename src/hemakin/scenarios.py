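"""Synthetic ground-truth scenarios emulating the experimental kinetics.

The reference measurements — tri-tissue leukemic and normal cell counts,
BM HSC/HPC counts, and the quiescent-HSC time course, sampled on days
0/7/10/12/14/21 with three replicates — exist only as figures in the source
study, so this module generates datasets with the same statistical and
qualitative structure from hand-calibrated generating models:

* ``default_scenario``   — tissue level: leukemic expansion in every tissue,
  PB normal counts rising after day 7, spleen normal counts peaking before
  day 21 then falling, BM normal counts declining to a day-21 minimum.
* ``hsc_hpc_scenario``   — BM primitive cells: HSC and HPC both decline,
  HPC much more sharply (differentiation blockade + stimulated death),
  driven by the default scenario's leukemic-BM trajectory as forcing.
* ``quiescence_scenario``— quiescent/active HSC split: the G0 fraction is
  40 % at baseline, nearly flat over the first three observation days, and
  exceeds 92 % from day 14 on, with the steepest rise between days 10 and
  14 (re-entry-on variant).

Noise model: each replicate is the noise-free value times a lognormal
factor with coefficient of variation ``cv`` (spread grows with magnitude,
counts stay positive); the dataset records the replicate mean and sample
SD.  cv = 0 returns the ground truth exactly with SD 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import presets
from .fitting import KineticsDataset, Series
from .model import ModelSpec, ParameterSet, apply_balance
from .simulate import OBS_DAYS, Trajectory, forcing_from_trajectory, observe, simulate

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "hsc_hpc_scenario",
    "quiescence_scenario",
    "generate",
    "scenario_truth",
    "scenario_trajectory",
    "leukemic_bm_forcing",
]


@dataclass
class SyntheticScenario:
    """A generating model plus observation schedule and noise model."""

    label: str
    spec: ModelSpec
    params: ParameterSet          # balance-resolved generating parameters
    x0: np.ndarray
    obs_days: tuple[float, ...] = OBS_DAYS
    cv: float = 0.15              # multiplicative lognormal noise CV
    n_replicates: int = 3
    series_keys: tuple = ()
    #: label of the scenario whose leukemic-BM trajectory forces this one
    forcing_from: str | None = None

    def __post_init__(self) -> None:
        if self.cv < 0 or self.n_replicates < 1:
            raise ValueError("scenario requires cv >= 0 and n >= 1")

    def with_noise(self, cv: float | None = None, n_replicates: int | None = None):
        return replace(self, cv=self.cv if cv is None else cv,
                       n_replicates=self.n_replicates if n_replicates is None
                       else n_replicates)


def default_scenario(cv: float = 0.15, n_replicates: int = 3) -> SyntheticScenario:
    """The calibrated tissue-level scenario (pb_coupled mobility)."""
    spec = presets.tissue_spec("pb_coupled")
    x0 = presets.tissue_x0(spec)
    params = apply_balance(spec, presets.tissue_truth(), x0)
    return SyntheticScenario(
        label="default", spec=spec, params=params, x0=x0, cv=cv,
        n_replicates=n_replicates, series_keys=presets.TISSUE_SERIES,
    )


def hsc_hpc_scenario(cv: float = 0.15, n_replicates: int = 3) -> SyntheticScenario:
    """BM HSC/HPC sub-model scenario, forced by the default leukemic-BM course."""
    spec = presets.hsc_spec()
    x0 = presets.hsc_x0(spec)
    params = apply_balance(spec, presets.hsc_truth(), x0)
    return SyntheticScenario(
        label="hsc_hpc", spec=spec, params=params, x0=x0, cv=cv,
        n_replicates=n_replicates,
        series_keys=(("BM", "HSC"), ("BM", "HPC")),
        forcing_from="default",
    )


def quiescence_scenario(g0_reentry: str = "on", cv: float = 0.15,
                        n_replicates: int = 3) -> SyntheticScenario:
    """Quiescent/active HSC scenario.  The generating model is always the
    re-entry-on variant; ``g0_reentry='off'`` returns the same observation
    schedule with the selective-exhaustion generating model for contrast
    experiments."""
    spec = presets.g0_spec(g0_reentry)
    x0 = presets.g0_x0(spec)
    if g0_reentry == "on":
        params = apply_balance(spec, presets.g0_truth(), x0)
    else:
        params = apply_balance(spec, _g0_off_truth(), x0)
    return SyntheticScenario(
        label=f"quiescence/{g0_reentry}", spec=spec, params=params, x0=x0, cv=cv,
        n_replicates=n_replicates,
        series_keys=(("BM", "HSC"), ("BM", "HSC_G0")),
        forcing_from="default",
    )


def _g0_off_truth() -> ParameterSet:
    """Selective-exhaustion counterpart: leukemia-stimulated active-HSC death,
    matched early trajectory (same activation suppression)."""
    base = presets.g0_truth()
    v = {k: val for k, val in base.values.items()
         if not k.startswith("BM.HSC_active.G0_reentry")}
    v.update({
        # quiescent cells barely activate: without re-entry the G0 pool has
        # no inflow, so only near-zero turnover keeps the early course flat
        "BM.HSC_G0.G0_exit.k": 0.001,
        "BM.HSC_G0.Death.k": 0.0005,
        "BM.HSC_active.Expn.k": 0.35,
        "BM.HSC_active.Death.coupling.beta": 4.0,
        "BM.HSC_active.Death.mod.theta_L": 6e5,
        "BM.HSC_active.Death.mod.h_L": 6.0,
    })
    return ParameterSet(values=v)


_FORCING_CACHE: dict[str, Trajectory] = {}


def scenario_trajectory(scenario: SyntheticScenario, grid_dt: float = 0.05,
                        use_cache: bool = True) -> Trajectory:
    """Ground-truth dense trajectory of a scenario (deterministic)."""
    forcing = None
    if scenario.forcing_from is not None:
        forcing = leukemic_bm_forcing(use_cache=use_cache)
    t1 = float(max(scenario.obs_days))
    return simulate(scenario.spec, scenario.params, scenario.x0, span=(0.0, t1),
                    obs_days=scenario.obs_days, grid_dt=grid_dt, forcing=forcing)


def leukemic_bm_forcing(use_cache: bool = True):
    """L(t): the default scenario's leukemic-BM trajectory as sub-model forcing."""
    if not use_cache or "default" not in _FORCING_CACHE:
        sc = default_scenario()
        _FORCING_CACHE["default"] = simulate(sc.spec, sc.params, sc.x0,
                                             span=(0.0, float(max(sc.obs_days))),
                                             obs_days=sc.obs_days)
    return forcing_from_trajectory(_FORCING_CACHE["default"], ("BM", "leukemic"))


def scenario_truth(scenario: SyntheticScenario) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free observations of every scenario series at the observation days."""
    traj = scenario_trajectory(scenario)
    obs = observe(traj, scenario.obs_days)
    return {tuple(k): obs[tuple(k)] for k in scenario.series_keys}


def generate(scenario: SyntheticScenario, seed: int = 0) -> KineticsDataset:
    """Simulate the ground truth and draw a noisy replicate dataset.

    Replicates are truth * LogNormal(mu, sigma) with E[factor] = 1 and
    CV = scenario.cv; the dataset records replicate means and sample SDs
    (ddof = 1).  cv = 0 reproduces the truth exactly with sd = 0.
    Deterministic for a fixed seed.
    """
    truth = scenario_truth(scenario)
    days = np.asarray(scenario.obs_days, dtype=float)
    rng = np.random.default_rng(seed)
    series: dict[tuple[str, str], Series] = {}
    n = scenario.n_replicates
    cv = scenario.cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    mu = -0.5 * sigma**2
    for key, vals in truth.items():
        if cv == 0 or n == 1:
            mean = vals.copy()
            sd = np.zeros_like(vals)
        else:
            factors = rng.lognormal(mean=mu, sigma=sigma, size=(n, len(vals)))
            reps = vals[None, :] * factors
            mean = reps.mean(axis=0)
            sd = reps.std(axis=0, ddof=1)
        series[key] = Series(days=days, mean=mean, sd=sd,
                             n=np.full(len(vals), n, dtype=int))
    return KineticsDataset(series=series, provenance=f"synthetic:{scenario.label}:seed={seed}")
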