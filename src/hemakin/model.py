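"""Declarative model specification and ODE right-hand-side assembly.

The model is a three-compartment system — peripheral blood (PB), spleen (SP)
and bone marrow (BM) — each carrying a leukemic and a normal hematopoietic
cell population, with optional nested sub-models for the BM primitive cells
(HSC/HPC) and for the quiescent/active HSC split (G0 level).  The count X of
every population evolves as

    dX/dt = f_Prolif - f_Death - f_Export + f_Import

where each f is an elementary rate law (see :mod:`hemakin.rates`) evaluated
on a driving population count and multiplied by a leukemic modifier K(L)
with L the leukemic burden of the same compartment.  Migration is restricted
to SP<->PB and BM<->PB edges: the spleen and the marrow communicate only
through the circulation.

A :class:`ModelSpec` lists the populations and processes; a
:class:`ParameterSet` carries the numeric parameter values (flat dotted
names) and their fitting bounds.  ``build_rhs`` compiles the pair into a
fast derivative function; ``reduce_to_control`` produces the leukemia-free
model by purging every ``.coupling.`` parameter to zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .rates import (
    FORM_KINDS,
    LeukemicModifier,
    RateForm,
    form_param_names,
    form_scale_param,
)

__all__ = [
    "ProcessSpec",
    "ModelSpec",
    "ParameterSet",
    "CompiledModel",
    "build_rhs",
    "compile_model",
    "apply_balance",
    "enumerate_structures",
    "reduce_to_control",
    "control_state",
    "validate_spec",
    "state_vector",
    "BalanceError",
    "ConfigurationError",
]

log = logging.getLogger(__name__)

PROCESS_KINDS = (
    "Prolif",
    "Death",
    "Export",
    "Import",
    "Expn",
    "Diff",
    "HSC_to_HPC",
    "G0_exit",
    "G0_reentry",
)

#: kinds that represent pure gain of their own pool (no pool is depleted)
GAIN_KINDS = frozenset({"Prolif", "Expn"})

MOBILITY_MODES = ("zero", "constant", "pb_coupled")

PopKey = tuple[str, str]  # (compartment, population)


class ConfigurationError(ValueError):
    """A model spec / parameter-set inconsistency."""


class BalanceError(ValueError):
    """The homeostatic closure produced an infeasible (negative) rate constant."""


def _pop_label(key: PopKey) -> str:
    return f"{key[0]}.{key[1]}"


@dataclass(frozen=True)
class ProcessSpec:
    """One cellular process: a rate law acting on a source and/or sink pool.

    ``source`` is depleted and ``sink`` replenished by the process; gain
    processes (Prolif, Expn) set source == sink and only replenish.  The rate
    law is evaluated on the ``driver`` population (default: the source, or
    the sink for source-free imports).  ``modifier`` names the direction of
    the leukemic influence; its driver is the leukemic population of the
    process's home compartment, or the exogenous forcing in sub-models.
    """

    kind: str
    source: PopKey | None
    sink: PopKey | None
    form_kind: str
    modifier: str = "none"
    driver: PopKey | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise ConfigurationError(f"unknown process kind {self.kind!r}")
        if self.form_kind not in FORM_KINDS:
            raise ConfigurationError(f"unknown rate-form kind {self.form_kind!r}")
        if self.modifier not in ("none", "suppressive", "stimulative"):
            raise ConfigurationError(f"unknown modifier direction {self.modifier!r}")
        if self.source is None and self.sink is None:
            raise ConfigurationError(f"{self.kind} process needs a source or a sink")
        if not self.name:
            home = self.sink if self.kind in ("Import", "HSC_to_HPC") else self.source
            home = home or self.sink or self.source
            object.__setattr__(self, "name", f"{_pop_label(home)}.{self.kind}")

    @property
    def home(self) -> PopKey:
        """The compartment/population the process is named for."""
        if self.kind in ("Import", "HSC_to_HPC") and self.sink is not None:
            return self.sink
        return self.source or self.sink

    @property
    def driver_key(self) -> PopKey:
        return self.driver or self.source or self.sink

    def param_names(self) -> list[str]:
        names = [f"{self.name}.{p}" for p in form_param_names(self.form_kind)]
        if self.modifier == "suppressive":
            names += [f"{self.name}.coupling.inv_theta_L", f"{self.name}.mod.h_L"]
        elif self.modifier == "stimulative":
            names += [
                f"{self.name}.coupling.beta",
                f"{self.name}.mod.theta_L",
                f"{self.name}.mod.h_L",
            ]
        return names


@dataclass
class ModelSpec:
    """Populations, processes and structural flags of one model variant."""

    populations: list[PopKey]
    processes: list[ProcessSpec]
    mobility_mode: str = "pb_coupled"
    g0_reentry: str = "off"
    hierarchy_level: str = "tissue"  # tissue | hsc_hpc | g0
    #: ordered homeostatic-closure assignments: (population, process name) —
    #: the process's scale parameter is derived so that the population is at
    #: steady state in the leukemia-free limit (see ``apply_balance``)
    balance: list[tuple[PopKey, str]] = field(default_factory=list)
    #: sub-models take the leukemic burden as an exogenous forcing L(t)
    uses_forcing: bool = False
    label: str = ""

    @property
    def compartments(self) -> list[str]:
        seen: list[str] = []
        for comp, _ in self.populations:
            if comp not in seen:
                seen.append(comp)
        return seen

    def process(self, name: str) -> ProcessSpec:
        for p in self.processes:
            if p.name == name:
                return p
        raise ConfigurationError(f"no process named {name!r}")

    def param_names(self) -> list[str]:
        out: list[str] = []
        for p in self.processes:
            out.extend(p.param_names())
        return out

    def copy(self) -> "ModelSpec":
        return replace(self, processes=list(self.processes), balance=list(self.balance))


@dataclass
class ParameterSet:
    """Flat map of dotted parameter names to values, with fitting bounds.

    A parameter is *free* when its bounds are a nondegenerate interval;
    parameters without bounds (or with lo == hi) are fixed.  Leukemic
    coupling strengths carry a ``.coupling.`` name segment so the control
    reduction can purge them collectively.
    """

    values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __setitem__(self, name: str, value: float) -> None:
        self.values[name] = value

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)

    def free_names(self) -> list[str]:
        return [n for n, (lo, hi) in self.bounds.items() if hi > lo]

    def check_bounds(self) -> None:
        for n, (lo, hi) in self.bounds.items():
            if n not in self.values:
                raise ConfigurationError(f"bounded parameter {n!r} has no value")
            v = self.values[n]
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ConfigurationError(f"parameter {n!r}={v} outside bounds [{lo}, {hi}]")

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.bounds))

    def purged(self) -> "ParameterSet":
        """All ``.coupling.`` parameters set to zero; everything else identical."""
        out = self.copy()
        for name in out.values:
            if ".coupling." in name:
                out.values[name] = 0.0
        return out


def state_vector(spec: ModelSpec, counts: dict[PopKey, float]) -> np.ndarray:
    """Build the ordered state array from a (compartment, population) -> count map."""
    x = np.zeros(len(spec.populations))
    for key, v in counts.items():
        if key not in spec.populations:
            raise ConfigurationError(f"unknown population {key}")
        x[spec.populations.index(key)] = v
    return x


# ---------------------------------------------------------------------------
# compilation

_FORM_CODE = {k: i for i, k in enumerate(FORM_KINDS)}
_MOD_CODE = {"none": 0, "suppressive": 1, "stimulative": 2}

try:  # optional JIT fast path; the pure-Python evaluator is the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=False)
    def _rhs_kernel(t, x, sub, add, drv, fc, fp, mc, mp, msrc, gate,
                    f_t, f_v, n_pop):  # pragma: no cover - exercised via rhs
        dx = np.zeros(n_pop)
        fval = np.interp(t, f_t, f_v) if f_t.size > 0 else 0.0
        if fval < 0.0:
            fval = 0.0
        for i in range(sub.size):
            xv = x[drv[i]]
            if xv < 0.0:
                xv = 0.0
            c = fc[i]
            if c == 0:
                r = fp[i, 0]
                if gate[i] >= 0:
                    xs = x[gate[i]]
                    if xs <= 0.0:
                        r = 0.0
                    elif xs < 1.0:  # ramp below one cell keeps the rhs Lipschitz
                        r *= xs
            elif c == 1:
                r = fp[i, 0] * xv
            elif c == 2:
                r = fp[i, 0] * -math.expm1(-xv / fp[i, 1])
            elif c == 3:
                r = fp[i, 0] * xv / (fp[i, 1] + xv) if xv > 0.0 else 0.0
            else:
                if xv > 0.0:
                    u = (xv / fp[i, 1]) ** fp[i, 2]
                    r = fp[i, 0] * u / (1.0 + u)
                else:
                    r = 0.0
            m = mc[i]
            if m != 0:
                if msrc[i] == -2:
                    L = fval
                else:
                    L = x[msrc[i]]
                    if L < 0.0:
                        L = 0.0
                if m == 1:
                    u = mp[i, 0] * L
                    if u > 0.0:
                        r /= 1.0 + u ** mp[i, 2]
                elif L > 0.0 and mp[i, 0] > 0.0:
                    u = (L / mp[i, 1]) ** mp[i, 2]
                    r *= 1.0 + mp[i, 0] * u / (1.0 + u)
            if sub[i] >= 0:
                dx[sub[i]] -= r
            if add[i] >= 0:
                dx[add[i]] += r
        return dx

except Exception:  # pragma: no cover
    _rhs_kernel = None


class CompiledModel:
    """A ModelSpec + ParameterSet compiled to flat arrays for fast evaluation.

    Exposes the full right-hand side (``rhs``), the per-process rate vector
    (``process_rates``) used by the mechanistic decomposition, and the signed
    incidence of each process on each population.
    """

    def __init__(self, spec: ModelSpec, params: ParameterSet, forcing=None):
        self.spec = spec
        self.params = params
        self.forcing = forcing
        if spec.uses_forcing and forcing is None:
            # burden defaults to zero: the sub-model control limit
            self.forcing = lambda t: 0.0
        self.names = [p.name for p in spec.processes]
        n = len(spec.populations)
        idx = {key: i for i, key in enumerate(spec.populations)}
        leuk_by_comp = {
            comp: idx.get((comp, "leukemic"), -1) for comp in spec.compartments
        }

        entries = []
        missing: list[str] = []
        for proc in spec.processes:
            for key in (proc.source, proc.sink, proc.driver):
                if key is not None and key not in idx:
                    raise ConfigurationError(
                        f"process {proc.name!r} references unknown population {key}"
                    )
            fp = []
            for pname in form_param_names(proc.form_kind):
                full = f"{proc.name}.{pname}"
                if full not in params:
                    missing.append(full)
                    fp.append(0.0)
                else:
                    fp.append(params[full])
            mod_code = _MOD_CODE[proc.modifier]
            if proc.modifier == "suppressive":
                mp = (
                    _req(params, f"{proc.name}.coupling.inv_theta_L", missing),
                    1.0,
                    _req(params, f"{proc.name}.mod.h_L", missing),
                )
            elif proc.modifier == "stimulative":
                mp = (
                    _req(params, f"{proc.name}.coupling.beta", missing),
                    _req(params, f"{proc.name}.mod.theta_L", missing),
                    _req(params, f"{proc.name}.mod.h_L", missing),
                )
            else:
                mp = (0.0, 1.0, 1.0)

            gain = proc.source is not None and proc.source == proc.sink
            sub = -1 if (gain or proc.source is None) else idx[proc.source]
            add = idx[proc.sink] if proc.sink is not None else -1
            drv = idx[proc.driver_key]
            # leukemic burden driving the modifier: the leukemic population of
            # the home compartment, or the exogenous forcing in sub-models
            if mod_code == 0:
                msrc = -1
            else:
                home_comp = proc.home[0]
                msrc = leuk_by_comp.get(home_comp, -1)
                if msrc == -1 and not spec.uses_forcing:
                    raise ConfigurationError(
                        f"process {proc.name!r} has a leukemic modifier but no "
                        f"leukemic population or forcing is available"
                    )
                if msrc == -1:
                    msrc = -2  # forcing
            # zero-order laws on consumptive processes are gated to zero when
            # the depleted pool is empty, preserving nonnegativity
            gate = sub if (proc.form_kind == "zero_order" and sub >= 0) else -1
            entries.append(
                (sub, add, drv, _FORM_CODE[proc.form_kind], tuple(fp), mod_code, mp, msrc, gate)
            )
        if missing:
            raise ConfigurationError(f"missing parameters: {sorted(set(missing))}")
        self._entries = entries
        self.n_pop = n
        # flat arrays for the JIT kernel
        m = len(entries)
        self._sub = np.array([e[0] for e in entries], dtype=np.int64)
        self._add = np.array([e[1] for e in entries], dtype=np.int64)
        self._drv = np.array([e[2] for e in entries], dtype=np.int64)
        self._fc = np.array([e[3] for e in entries], dtype=np.int64)
        self._fp = np.zeros((m, 3))
        for i, e in enumerate(entries):
            self._fp[i, : len(e[4])] = e[4]
        self._mc = np.array([e[5] for e in entries], dtype=np.int64)
        self._mp = np.array([e[6] for e in entries], dtype=float)
        self._msrc = np.array([e[7] for e in entries], dtype=np.int64)
        self._gate = np.array([e[8] for e in entries], dtype=np.int64)
        needs_forcing = bool(np.any(self._msrc == -2))
        grid = getattr(self.forcing, "grid", None) if self.forcing is not None else None
        if needs_forcing and grid is not None:
            self._f_t, self._f_v = grid
        elif not needs_forcing:
            self._f_t = np.empty(0)
            self._f_v = np.empty(0)
        else:
            self._f_t = None  # forcing without a grid: Python path only
        self._use_kernel = _rhs_kernel is not None and self._f_t is not None

    def process_rates(self, t: float, x: np.ndarray) -> np.ndarray:
        """Nonnegative rate of every process at state ``x`` (cells/day)."""
        forcing = self.forcing
        out = np.empty(len(self._entries))
        for i, (sub, add, drv, fc, fp, mc, mp, msrc, gate) in enumerate(self._entries):
            xv = x[drv]
            if xv < 0.0:
                xv = 0.0
            if fc == 0:
                r = fp[0]
                if gate >= 0:
                    xs = x[gate]
                    if xs <= 0.0:
                        r = 0.0
                    elif xs < 1.0:  # linear ramp below one cell: Lipschitz rhs
                        r = r * xs
            elif fc == 1:
                r = fp[0] * xv
            elif fc == 2:
                r = fp[0] * -math.expm1(-xv / fp[1])
            elif fc == 3:
                r = fp[0] * xv / (fp[1] + xv) if xv > 0.0 else 0.0
            else:  # hill
                if xv > 0.0:
                    u = (xv / fp[1]) ** fp[2]
                    r = fp[0] * u / (1.0 + u)
                else:
                    r = 0.0
            if mc != 0:
                L = forcing(t) if msrc == -2 else x[msrc]
                if L < 0.0:
                    L = 0.0
                if mc == 1:
                    u = mp[0] * L
                    if u > 0.0:
                        r /= 1.0 + u ** mp[2]
                elif L > 0.0 and mp[0] > 0.0:
                    u = (L / mp[1]) ** mp[2]
                    r *= 1.0 + mp[0] * u / (1.0 + u)
            out[i] = r
        return out

    def signed_contributions(self, t: float, x: np.ndarray) -> np.ndarray:
        """(n_process, n_pop) signed rate matrix: column sums give the rhs."""
        rates = self.process_rates(t, x)
        out = np.zeros((len(self._entries), self.n_pop))
        for i, (sub, add, *_rest) in enumerate(self._entries):
            if sub >= 0:
                out[i, sub] -= rates[i]
            if add >= 0:
                out[i, add] += rates[i]
        return out

    def rhs_py(self, t: float, x: np.ndarray) -> np.ndarray:
        """Pure-Python right-hand side (reference implementation)."""
        rates = self.process_rates(t, x)
        dx = np.zeros(self.n_pop)
        for i, (sub, add, *_rest) in enumerate(self._entries):
            r = rates[i]
            if sub >= 0:
                dx[sub] -= r
            if add >= 0:
                dx[add] += r
        return dx

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        if self._use_kernel:
            return _rhs_kernel(t, x, self._sub, self._add, self._drv, self._fc,
                               self._fp, self._mc, self._mp, self._msrc,
                               self._gate, self._f_t, self._f_v, self.n_pop)
        return self.rhs_py(t, x)


def _req(params: ParameterSet, name: str, missing: list[str]) -> float:
    if name not in params:
        missing.append(name)
        return 0.0
    return params[name]


def compile_model(spec: ModelSpec, params: ParameterSet, forcing=None) -> CompiledModel:
    return CompiledModel(spec, params, forcing)


def build_rhs(spec: ModelSpec, params: ParameterSet, forcing=None):
    """Return the derivative function f(t, x) -> dx/dt for the assembled model."""
    return compile_model(spec, params, forcing).rhs


# ---------------------------------------------------------------------------
# homeostatic closure

def apply_balance(spec: ModelSpec, params: ParameterSet, x0: np.ndarray) -> ParameterSet:
    """Derive the designated scale parameters from control steady state.

    For each ``(population, process)`` pair in ``spec.balance`` (in order),
    the process's multiplicative scale parameter is set so that the
    population's net rate vanishes at the leukemia-free version of ``x0``
    (leukemic counts zeroed, all modifiers at K(0) = 1).  This encodes
    baseline hematopoietic homeostasis: under control conditions the normal
    populations hold steady.  Raises :class:`BalanceError` when the balance
    would require a negative rate constant.
    """
    out = params.copy()
    x_ctrl = np.array(x0, dtype=float)
    for i, (comp, pop) in enumerate(spec.populations):
        if pop == "leukemic":
            x_ctrl[i] = 0.0
    idx = {key: i for i, key in enumerate(spec.populations)}
    for pool, proc_name in spec.balance:
        proc = spec.process(proc_name)
        if pool not in idx:
            raise ConfigurationError(f"balance pool {pool} not in populations")
        pi = idx[pool]
        scale_name = f"{proc.name}.{form_scale_param(proc.form_kind)}"
        # net contribution of all *other* processes to this pool, control limit
        probe = out.copy()
        probe[scale_name] = 0.0
        cm = CompiledModel(spec, probe, forcing=(lambda t: 0.0) if spec.uses_forcing else None)
        net_others = cm.rhs(0.0, x_ctrl)[pi]
        # unit-scale rate and sign of the balance process on this pool
        unit = out.copy()
        unit[scale_name] = 1.0
        cmu = CompiledModel(spec, unit, forcing=(lambda t: 0.0) if spec.uses_forcing else None)
        contrib = cmu.signed_contributions(0.0, x_ctrl)[cmu.names.index(proc_name), pi]
        if contrib == 0.0:
            raise BalanceError(
                f"balance process {proc_name!r} has zero unit rate for pool {pool} "
                f"at the control state"
            )
        scale = -net_others / contrib
        if scale < 0:
            raise BalanceError(
                f"balance for {pool} via {proc_name!r} requires negative scale {scale:.3g}"
            )
        out[scale_name] = scale
    return out


# ---------------------------------------------------------------------------
# structure enumeration and control reduction

def enumerate_structures(
    template: ModelSpec,
    candidates: dict[str, list[str]],
    cap: int = 256,
) -> list[ModelSpec]:
    """Cartesian product of candidate rate-form assignments.

    ``candidates`` maps process names to lists of candidate form kinds;
    unlisted processes keep their template form.  The output order is
    deterministic: lexicographic by process name, then by form kind.  The
    list is truncated at ``cap`` with a logged warning.
    """
    if cap < 1:
        raise ConfigurationError("cap must be >= 1")
    for name, kinds in candidates.items():
        template.process(name)  # raises for unknown names
        if not kinds:
            raise ConfigurationError(f"empty candidate list for process {name!r}")
    names = sorted(candidates)
    kind_lists = [sorted(set(candidates[n])) for n in names]
    total = 1
    for kl in kind_lists:
        total *= len(kl)
    if total > cap:
        log.warning("structure enumeration truncated: %d candidates, cap %d", total, cap)
    out: list[ModelSpec] = []
    for combo in itertools.product(*kind_lists):
        if len(out) >= cap:
            break
        assignment = dict(zip(names, combo))
        procs = [
            replace(p, form_kind=assignment[p.name]) if p.name in assignment else p
            for p in template.processes
        ]
        out.append(replace(template.copy(), processes=procs))
    return out


def subsystem(spec: ModelSpec, pops) -> ModelSpec:
    """The closed sub-model on a population subset.

    Keeps exactly the processes whose source, sink and driver all lie in the
    subset; balance assignments outside the subset are dropped.  Intended
    for autonomous subsystems (e.g. the leukemic populations, which normal
    cells never influence), where the restriction is dynamically exact.
    """
    pops = [tuple(p) for p in pops]
    missing = [p for p in pops if p not in spec.populations]
    if missing:
        raise ConfigurationError(f"unknown populations {missing}")
    keep = []
    pset = set(pops)
    for proc in spec.processes:
        refs = [k for k in (proc.source, proc.sink, proc.driver) if k is not None]
        if all(k in pset for k in refs):
            keep.append(proc)
    balance = [(pool, name) for pool, name in spec.balance
               if pool in pset and any(p.name == name for p in keep)]
    return ModelSpec(populations=pops, processes=keep,
                     mobility_mode=spec.mobility_mode, g0_reentry=spec.g0_reentry,
                     hierarchy_level=spec.hierarchy_level, balance=balance,
                     uses_forcing=spec.uses_forcing,
                     label=f"{spec.label}/subsystem")


def control_state(spec: ModelSpec, x0: np.ndarray) -> np.ndarray:
    """Copy of ``x0`` with every leukemic population zeroed."""
    out = np.array(x0, dtype=float)
    for i, (_comp, pop) in enumerate(spec.populations):
        if pop == "leukemic":
            out[i] = 0.0
    return out


def reduce_to_control(
    spec: ModelSpec, params: ParameterSet, x0: np.ndarray | None = None
):
    """The leukemia-free model: coupling strengths purged to zero.

    Every ``.coupling.`` parameter is set to 0 (so every leukemic modifier
    becomes K == 1) and, when an initial state is given, leukemic counts are
    zeroed.  Nothing else changes.  Idempotent.
    """
    params_c = params.purged()
    if x0 is None:
        return spec, params_c, None
    return spec, params_c, control_state(spec, x0)


# ---------------------------------------------------------------------------
# validation

def validate_spec(spec: ModelSpec) -> list[str]:
    """Structural invariant check; returns human-readable violations (empty = valid)."""
    out: list[str] = []
    pops = set(spec.populations)
    if spec.mobility_mode not in MOBILITY_MODES:
        out.append(f"unknown mobility mode {spec.mobility_mode!r}")
    names = [p.name for p in spec.processes]
    for name in set(names):
        if names.count(name) > 1:
            out.append(f"duplicate process name {name!r}")
    for p in spec.processes:
        for key in (p.source, p.sink, p.driver):
            if key is not None and key not in pops:
                out.append(f"process {p.name!r} references unknown population {key}")
        if p.kind == "Prolif" and p.home == ("PB", "normal"):
            out.append("PB normal proliferation forbidden (no primitive cells in circulation)")
        if p.kind in ("Export", "Import") and p.source and p.sink:
            comps = {p.source[0], p.sink[0]}
            if "PB" not in comps and len(comps) == 2:
                out.append(
                    f"process {p.name!r}: direct {p.source[0]}<->{p.sink[0]} migration; "
                    f"tissues communicate only via PB"
                )
        if p.kind == "HSC_to_HPC":
            if p.source is None or p.source[1] not in ("HSC", "HSC_active"):
                out.append(f"process {p.name!r}: HSC_to_HPC source must be HSC or HSC_active")
            if p.sink is None or p.sink[1] != "HPC":
                out.append(f"process {p.name!r}: HSC_to_HPC sink must be HPC")
    has_g0 = any(pop in ("HSC_G0", "HSC_active") for _c, pop in spec.populations)
    if has_g0 and spec.hierarchy_level != "g0":
        out.append("G0 populations present but hierarchy_level is not 'g0'")
    has_reentry = any(p.kind == "G0_reentry" for p in spec.processes)
    if has_reentry != (spec.g0_reentry == "on"):
        out.append("G0_reentry process present iff g0_reentry flag is 'on'")
    for pool, proc_name in spec.balance:
        if pool not in pops:
            out.append(f"balance pool {pool} not in populations")
        if proc_name not in names:
            out.append(f"balance process {proc_name!r} not in processes")
    return out
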