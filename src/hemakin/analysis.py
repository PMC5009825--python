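"""Parametric analysis: mechanism decomposition, fluxes, and model selection.

Parametric analysis projects a fitted trajectory onto its acting factors:
every process rate f_i(X(t), K(L(t))) is evaluated along the trajectory, so
the net change of each population decomposes exactly into signed mechanism
rates (proliferation, death, import, export, expansion, differentiation).
Interval fluxes integrate a single process rate over consecutive day
intervals — e.g. the absolute number of HSCs differentiating into HPCs per
day interval.  Model selection compares the per-restart fit errors of two
variants with a one-tailed Welch t-test: the winner is the variant whose
mean error is significantly lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from .fitting import FitResult, KineticsDataset, multi_restart
from .model import ModelSpec, ParameterSet, compile_model
from .simulate import Trajectory

__all__ = [
    "DecompositionTable",
    "FluxTable",
    "FactorRanking",
    "SelectionResult",
    "decompose",
    "interval_flux",
    "rank_factors",
    "compare_variants",
    "run_selection_experiment",
    "day_intervals",
]


@dataclass
class DecompositionTable:
    """Signed per-process rate series along a trajectory.

    ``rates`` holds the nonnegative process rates (cells/day) on the time
    grid; ``signed`` maps each population to a DataFrame of the signed
    contributions of its processes, whose row sums equal dX/dt.
    """

    times: np.ndarray
    rates: pd.DataFrame                      # columns = process names
    signs: dict[str, dict[tuple[str, str], int]]
    populations: list[tuple[str, str]]

    def signed_sum(self, population) -> np.ndarray:
        pop = tuple(population)
        total = np.zeros(len(self.times))
        for proc, signs in self.signs.items():
            sgn = signs.get(pop, 0)
            if sgn:
                total = total + sgn * self.rates[proc].to_numpy()
        return total

    def signed_frame(self, population) -> pd.DataFrame:
        pop = tuple(population)
        cols = {}
        for proc, signs in self.signs.items():
            sgn = signs.get(pop, 0)
            if sgn:
                cols[proc] = sgn * self.rates[proc].to_numpy()
        return pd.DataFrame(cols, index=pd.Index(self.times, name="day"))

    def to_frame(self) -> pd.DataFrame:
        out = self.rates.copy()
        out.insert(0, "day", self.times)
        return out


@dataclass
class FluxTable:
    """Per-interval absolute cell flux of one process (cells per interval)."""

    process: str
    intervals: list[tuple[float, float]]
    flux: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_start": [a for a, _ in self.intervals],
             "t_end": [b for _, b in self.intervals],
             "flux": self.flux, "process": self.process}
        )


@dataclass
class FactorRanking:
    """Processes of one population ranked by mean |rate| over a window."""

    population: tuple[str, str]
    window: tuple[float, float]
    table: pd.DataFrame  # columns: process, mean_abs_rate, amplitude, rank


@dataclass
class SelectionResult:
    """One-tailed Welch t-test between two variants' restart error samples."""

    label_a: str
    label_b: str
    errors_a: np.ndarray
    errors_b: np.ndarray
    t: float
    p: float
    winner: str
    alpha: float = 0.05
    degenerate: bool = False
    flavor: str = "welch one-tailed (a lower)"


def decompose(
    spec: ModelSpec,
    params: ParameterSet,
    traj: Trajectory,
    times=None,
    forcing=None,
) -> DecompositionTable:
    """Evaluate every process rate along the trajectory.

    ``spec``/``params`` must be those that produced ``traj``; the signed sum
    of a population's process rates then equals its time derivative.
    Default grid: 0.1-day spacing over the trajectory span.
    """
    if times is None:
        times = np.arange(traj.t[0], traj.t[-1] + 0.05, 0.1)
    times = np.asarray(times, dtype=float)
    if times.min() < traj.t[0] - 1e-9 or times.max() > traj.t[-1] + 1e-9:
        raise ValueError("decomposition times outside the trajectory span")
    cm = compile_model(spec, params, forcing)
    if list(spec.populations) != list(traj.populations):
        raise ValueError("spec and trajectory populations disagree")
    states = traj.at(times)
    n_proc = len(cm.names)
    vals = np.empty((len(times), n_proc))
    for i, t in enumerate(times):
        vals[i] = cm.process_rates(t, states[i])
    rates = pd.DataFrame(vals, columns=cm.names)
    signs: dict[str, dict[tuple[str, str], int]] = {}
    for proc, entry in zip(spec.processes, cm._entries):
        sub, add = entry[0], entry[1]
        d: dict[tuple[str, str], int] = {}
        if sub >= 0:
            d[tuple(spec.populations[sub])] = -1
        if add >= 0:
            d[tuple(spec.populations[add])] = d.get(tuple(spec.populations[add]), 0) + 1
        signs[proc.name] = d
    return DecompositionTable(times=times, rates=rates, signs=signs,
                              populations=list(spec.populations))


def day_intervals(t_end: int = 21) -> list[tuple[float, float]]:
    """The consecutive unit intervals [day i-1, day i] for i = 1..t_end."""
    return [(float(i - 1), float(i)) for i in range(1, t_end + 1)]


def interval_flux(
    spec: ModelSpec,
    params: ParameterSet,
    traj: Trajectory,
    process: str,
    intervals=None,
    forcing=None,
) -> FluxTable:
    """Integral of one process rate over each interval (adaptive quadrature
    on the trajectory's dense output)."""
    intervals = intervals or day_intervals(int(round(traj.t[-1])))
    cm = compile_model(spec, params, forcing)
    try:
        pi = cm.names.index(process)
    except ValueError:
        raise ValueError(f"unknown process {process!r}") from None

    def rate(t: float) -> float:
        x = traj.at(t)[0]
        return cm.process_rates(t, x)[pi]

    flux = np.empty(len(intervals))
    for i, (a, b) in enumerate(intervals):
        if a < traj.t[0] - 1e-9 or b > traj.t[-1] + 1e-9:
            raise ValueError(f"interval [{a}, {b}] outside the trajectory span")
        flux[i], _err = quad(rate, a, b, limit=200, epsabs=1e-10, epsrel=1e-10)
    return FluxTable(process=process, intervals=list(intervals), flux=flux)


def rank_factors(
    dec: DecompositionTable,
    population,
    window: tuple[float, float] | None = None,
) -> FactorRanking:
    """Rank a population's processes by mean |rate|; report the variation
    amplitude (max - min over the window) alongside.  Deterministic
    tie-break: lexicographic by process name."""
    pop = tuple(population)
    window = window or (float(dec.times[0]), float(dec.times[-1]))
    mask = (dec.times >= window[0] - 1e-9) & (dec.times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("empty analysis window")
    rows = []
    for proc, signs in dec.signs.items():
        if pop not in signs:
            continue
        r = dec.rates[proc].to_numpy()[mask]
        rows.append({"process": proc,
                     "mean_abs_rate": float(np.mean(np.abs(r))),
                     "amplitude": float(r.max() - r.min())})
    table = pd.DataFrame(rows).sort_values(
        ["mean_abs_rate", "process"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return FactorRanking(population=pop, window=window, table=table)


def compare_variants(errors_a, errors_b, alternative: str = "a_lower",
                     alpha: float = 0.05, label_a: str = "A",
                     label_b: str = "B") -> SelectionResult:
    """One-tailed Welch (unequal-variance) t-test on two error samples.

    ``alternative='a_lower'`` tests whether variant A's mean error is lower;
    the winner is the lower-mean variant when p < alpha, else inconclusive.
    Degenerate identical zero-variance samples yield p = 0.5 with a flag.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each error sample needs length >= 2")
    if alternative not in ("a_lower", "b_lower"):
        raise ValueError("alternative must be 'a_lower' or 'b_lower'")
    if np.std(a) == 0 and np.std(b) == 0 and np.array_equal(np.sort(a), np.sort(b)):
        return SelectionResult(label_a, label_b, a, b, t=0.0, p=0.5,
                               winner="inconclusive", alpha=alpha, degenerate=True)
    side = "less" if alternative == "a_lower" else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=side)
    t, p = float(res.statistic), float(res.pvalue)
    if p < alpha:
        winner = label_a if alternative == "a_lower" else label_b
    else:
        winner = "inconclusive"
    return SelectionResult(label_a, label_b, a, b, t=t, p=p, winner=winner,
                           alpha=alpha)


@dataclass
class SelectionExperiment:
    """All restart fits plus the pairwise tests of one selection experiment."""

    fits: dict[str, list[FitResult]]
    errors: dict[str, np.ndarray]
    tests: dict[tuple[str, str], SelectionResult]
    contested_series: list[tuple[str, str]] | None = None
    seeds: dict[str, list[int]] = field(default_factory=dict)


def run_selection_experiment(
    data: KineticsDataset,
    variants: dict[str, callable],
    n_restarts: int = 10,
    seed0: int = 0,
    contested_series=None,
    alpha: float = 0.05,
) -> SelectionExperiment:
    """Multi-restart each variant on the same data and test all pairs.

    ``variants`` maps labels to fit callables ``fit_fn(seed) -> FitResult``
    (typically closures over a spec/template/stages).  The error sample of a
    variant is its per-restart aggregate objective, restricted to
    ``contested_series`` when given.
    """
    if len(variants) < 2:
        raise ValueError("selection needs at least two variants")
    fits: dict[str, list[FitResult]] = {}
    errors: dict[str, np.ndarray] = {}
    seeds: dict[str, list[int]] = {}
    for label, fit_fn in variants.items():
        results = multi_restart(fit_fn, n_restarts, seed0)
        fits[label] = results
        seeds[label] = [r.seed for r in results]
        if contested_series is not None:
            errors[label] = np.array([r.objective_on(contested_series) for r in results])
        else:
            errors[label] = np.array([r.objective for r in results])
    tests: dict[tuple[str, str], SelectionResult] = {}
    labels = list(variants)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ea, eb = errors[la], errors[lb]
            alt = "a_lower" if ea.mean() <= eb.mean() else "b_lower"
            tests[(la, lb)] = compare_variants(ea, eb, alternative=alt, alpha=alpha,
                                               label_a=la, label_b=lb)
    return SelectionExperiment(fits=fits, errors=errors, tests=tests,
                               contested_series=(list(map(tuple, contested_series))
                                                 if contested_series else None),
                               seeds=seeds)
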