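"""Canonical model structures, ground-truth parameters, bounds and stages.

This module ships the default tri-tissue model of hematopoiesis under AML
and its two nested sub-models (HSC/HPC, quiescent/active HSC), together
with the hand-calibrated parameter values that define the synthetic study
conditions, the fitting bounds for every free parameter, and the staged
(hierarchical) fitting plans.

Model sketch (pb_coupled mobility, the full variant):

* Leukemic cells proliferate in SP and BM (first-order growth with a
  suppressive self-crowding modifier, i.e. logistic-like), migrate
  tissue -> PB -> tissue, and die in PB.  Their dynamics are autonomous.
* Normal cells proliferate in SP (leukemia-stimulated, a compensatory
  response) and BM (leukemia-suppressed), die in all three tissues, and
  migrate via PB; BM export is leukemia-stimulated (escape from the
  deteriorating marrow).  PB normal cells do not proliferate.
* One scale parameter per normal population is *derived*, not fitted: the
  homeostatic closure solves it from the control (leukemia-free) steady
  state at the initial counts, so every parameterization reproduces steady
  normal hematopoiesis when the leukemic couplings are purged.

Mobility variants: ``zero`` removes all migration; ``constant`` replaces
imports by zero-order constants decoupled from PB and sends exports to an
external sink (no mass balance); ``pb_coupled`` uses mass-balanced
first-order transfers with imports driven by the PB count.
"""

from __future__ import annotations

import numpy as np

from .model import ModelSpec, ParameterSet, ProcessSpec

__all__ = [
    "tissue_spec",
    "tissue_truth",
    "tissue_x0",
    "tissue_bounds",
    "tissue_stages",
    "hsc_spec",
    "hsc_truth",
    "hsc_x0",
    "hsc_bounds",
    "hsc_stages",
    "g0_spec",
    "g0_truth",
    "g0_x0",
    "g0_bounds",
    "g0_stages",
    "TISSUE_SERIES",
    "LEUKEMIC_SERIES",
    "NORMAL_SERIES",
]

PB, SP, BM = "PB", "SP", "BM"

LEUKEMIC_SERIES = ((PB, "leukemic"), (SP, "leukemic"), (BM, "leukemic"))
NORMAL_SERIES = ((PB, "normal"), (SP, "normal"), (BM, "normal"))
TISSUE_SERIES = LEUKEMIC_SERIES + NORMAL_SERIES


# ---------------------------------------------------------------------------
# tissue level

def tissue_spec(mobility_mode: str = "pb_coupled") -> ModelSpec:
    """The canonical tri-tissue model in one of the three mobility variants."""
    pops = [
        (PB, "leukemic"), (SP, "leukemic"), (BM, "leukemic"),
        (PB, "normal"), (SP, "normal"), (BM, "normal"),
    ]
    procs: list[ProcessSpec] = []

    # --- leukemic cells (autonomous)
    for comp in (SP, BM):
        procs.append(ProcessSpec("Prolif", (comp, "leukemic"), (comp, "leukemic"),
                                 "first_order", modifier="suppressive"))
    procs.append(ProcessSpec("Death", (PB, "leukemic"), None, "first_order"))
    if mobility_mode == "pb_coupled":
        for comp in (SP, BM):
            procs.append(ProcessSpec("Export", (comp, "leukemic"), (PB, "leukemic"),
                                     "first_order"))
            procs.append(ProcessSpec("Import", (PB, "leukemic"), (comp, "leukemic"),
                                     "first_order"))
    elif mobility_mode == "constant":
        for comp in (SP, BM, PB):
            procs.append(ProcessSpec("Export", (comp, "leukemic"), None, "first_order"))
            procs.append(ProcessSpec("Import", None, (comp, "leukemic"), "zero_order"))
    elif mobility_mode == "zero":
        # with no circulation the PB blast pool must sustain itself
        procs.append(ProcessSpec("Prolif", (PB, "leukemic"), (PB, "leukemic"),
                                 "first_order", modifier="suppressive"))
    else:
        raise ValueError(f"unknown mobility mode {mobility_mode!r}")

    # --- normal cells.  Spleen death carries no leukemic modifier: in this
    # model family the spleen rise-and-fall is a circulation effect (import
    # tracking the PB pool), not a local death response.
    procs.append(ProcessSpec("Prolif", (SP, "normal"), (SP, "normal"),
                             "first_order", modifier="stimulative"))
    procs.append(ProcessSpec("Death", (SP, "normal"), None, "first_order"))
    procs.append(ProcessSpec("Prolif", (BM, "normal"), (BM, "normal"),
                             "first_order", modifier="suppressive"))
    procs.append(ProcessSpec("Death", (BM, "normal"), None, "first_order"))
    procs.append(ProcessSpec("Death", (PB, "normal"), None, "first_order"))
    if mobility_mode == "pb_coupled":
        procs.append(ProcessSpec("Export", (SP, "normal"), (PB, "normal"), "first_order"))
        procs.append(ProcessSpec("Import", (PB, "normal"), (SP, "normal"), "first_order"))
        procs.append(ProcessSpec("Export", (BM, "normal"), (PB, "normal"), "first_order",
                                 modifier="stimulative"))
        procs.append(ProcessSpec("Import", (PB, "normal"), (BM, "normal"), "first_order"))
    elif mobility_mode == "constant":
        for comp in (SP, BM, PB):
            procs.append(ProcessSpec("Export", (comp, "normal"), None, "first_order",
                                     modifier="stimulative" if comp == BM else "none"))
            procs.append(ProcessSpec("Import", None, (comp, "normal"), "zero_order"))

    balance = [
        ((SP, "normal"), "SP.normal.Prolif"),
        ((BM, "normal"), "BM.normal.Prolif"),
        ((PB, "normal"), "PB.normal.Death"),
    ]
    return ModelSpec(populations=pops, processes=procs, mobility_mode=mobility_mode,
                     hierarchy_level="tissue", balance=balance,
                     label=f"tissue/{mobility_mode}")


def tissue_x0(spec: ModelSpec | None = None) -> np.ndarray:
    """Initial counts at leukemia induction (day 0), cells."""
    counts = {
        (PB, "leukemic"): 2e2, (SP, "leukemic"): 5e2, (BM, "leukemic"): 1e3,
        (PB, "normal"): 1e4, (SP, "normal"): 5e4, (BM, "normal"): 1e5,
    }
    spec = spec or tissue_spec()
    return np.array([counts[k] for k in spec.populations])


def tissue_truth() -> ParameterSet:
    """Hand-calibrated generating parameters for the pb_coupled variant.

    These values define the synthetic study conditions: leukemic expansion in
    all tissues, a PB normal rise after day 7, a spleen normal rise-then-fall
    peaking before day 21, and a BM normal decline to a day-21 minimum.
    Derived (homeostatic) scales are filled in by ``apply_balance``.
    """
    v = {
        # leukemic growth: logistic-like per tissue
        "SP.leukemic.Prolif.k": 0.62,
        "SP.leukemic.Prolif.coupling.inv_theta_L": 1.0 / 8e5,
        "SP.leukemic.Prolif.mod.h_L": 2.0,
        "BM.leukemic.Prolif.k": 0.70,
        "BM.leukemic.Prolif.coupling.inv_theta_L": 1.0 / 6e5,
        "BM.leukemic.Prolif.mod.h_L": 2.0,
        "PB.leukemic.Death.k": 0.30,
        "SP.leukemic.Export.k": 0.06,
        "BM.leukemic.Export.k": 0.08,
        "SP.leukemic.Import.k": 0.10,
        "BM.leukemic.Import.k": 0.12,
        # normal cells
        "SP.normal.Prolif.k": 0.0,            # derived (SP balance)
        "SP.normal.Prolif.coupling.beta": 0.05,
        "SP.normal.Prolif.mod.theta_L": 1e5,
        "SP.normal.Prolif.mod.h_L": 2.0,
        "SP.normal.Death.k": 0.50,
        "BM.normal.Prolif.k": 0.0,            # derived (BM balance)
        "BM.normal.Prolif.coupling.inv_theta_L": 1.0 / 3e5,
        "BM.normal.Prolif.mod.h_L": 2.0,
        "BM.normal.Death.k": 0.12,
        "PB.normal.Death.k": 0.0,             # derived (PB balance)
        "SP.normal.Export.k": 0.2,
        "SP.normal.Import.k": 1.2,
        "BM.normal.Export.k": 0.08,
        "BM.normal.Export.coupling.beta": 4.5,
        "BM.normal.Export.mod.theta_L": 4e5,
        "BM.normal.Export.mod.h_L": 3.0,
        "BM.normal.Import.k": 0.1,
    }
    return ParameterSet(values=v)


#: fixed Hill coefficients are not fitted; thresholds and strengths are.
_RATE_BOUNDS = (1e-3, 3.0)
_BETA_BOUNDS = (0.0, 6.0)
_THETA_BOUNDS = (1e3, 5e6)
_INV_THETA_BOUNDS = (1e-8, 1e-3)


def tissue_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    """Fitting bounds for every free parameter of a tissue-level variant.

    Hill coefficients (``.mod.h_L``) and derived (balance) scales are fixed;
    rate constants, coupling strengths and thresholds are free.  Zero-order
    import constants (constant-mobility variant) are bounded in cells/day.
    """
    derived = {f"{name}.{'k'}" for _pool, name in spec.balance}
    out: dict[str, tuple[float, float]] = {}
    for proc in spec.processes:
        for full in proc.param_names():
            leaf = full.rsplit(".", 1)[-1]
            if full in derived or leaf == "h_L":
                continue
            if ".coupling.beta" in full:
                out[full] = _BETA_BOUNDS
            elif ".coupling.inv_theta_L" in full:
                out[full] = _INV_THETA_BOUNDS
            elif ".mod.theta_L" in full:
                out[full] = _THETA_BOUNDS
            elif proc.form_kind == "zero_order":
                out[full] = (0.0, 3e4)  # cells/day
            else:
                out[full] = _RATE_BOUNDS
    return out


def tissue_stages(spec: ModelSpec):
    """Hierarchical fitting plan: leukemic parameters first, then normal.

    Leukemic dynamics are autonomous in the model (normal cells never enter
    leukemic rates), so the first stage fits the leukemic parameters on the
    closed leukemic subsystem; the normal-cell stage then fits the full
    model conditionally on them.
    """
    bounds = tissue_bounds(spec)
    leuk = [n for n in bounds if ".leukemic." in n]
    norm = [n for n in bounds if ".normal." in n]
    return [
        (leuk, list(LEUKEMIC_SERIES), list(LEUKEMIC_SERIES)),
        (norm, list(NORMAL_SERIES)),
    ]


# ---------------------------------------------------------------------------
# HSC/HPC sub-model (BM primitive cells, exogenous leukemic-BM forcing)

def hsc_spec() -> ModelSpec:
    pops = [(BM, "HSC"), (BM, "HPC")]
    procs = [
        ProcessSpec("Expn", (BM, "HSC"), (BM, "HSC"), "first_order",
                    modifier="suppressive"),
        ProcessSpec("HSC_to_HPC", (BM, "HSC"), (BM, "HPC"), "first_order",
                    modifier="suppressive", name="BM.HSC.HSC_to_HPC"),
        ProcessSpec("Death", (BM, "HSC"), None, "first_order"),
        ProcessSpec("Diff", (BM, "HPC"), None, "first_order",
                    modifier="suppressive"),
        ProcessSpec("Death", (BM, "HPC"), None, "first_order",
                    modifier="stimulative"),
    ]
    balance = [
        ((BM, "HSC"), "BM.HSC.Expn"),
        ((BM, "HPC"), "BM.HPC.Diff"),
    ]
    return ModelSpec(populations=pops, processes=procs, hierarchy_level="hsc_hpc",
                     balance=balance, uses_forcing=True, label="hsc_hpc")


def hsc_x0(spec: ModelSpec | None = None) -> np.ndarray:
    return np.array([5e3, 5e4])  # HSC, HPC


def hsc_truth() -> ParameterSet:
    v = {
        "BM.HSC.Expn.k": 0.0,                    # derived (HSC balance)
        "BM.HSC.Expn.coupling.inv_theta_L": 1.0 / 1.2e5,
        "BM.HSC.Expn.mod.h_L": 3.0,
        "BM.HSC.HSC_to_HPC.k": 0.55,
        "BM.HSC.HSC_to_HPC.coupling.inv_theta_L": 1.0 / 1.8e5,
        "BM.HSC.HSC_to_HPC.mod.h_L": 3.0,
        "BM.HSC.Death.k": 0.01,
        "BM.HPC.Diff.k": 0.0,                    # derived (HPC balance)
        "BM.HPC.Diff.coupling.inv_theta_L": 1.0 / 6e5,
        "BM.HPC.Diff.mod.h_L": 3.0,
        "BM.HPC.Death.k": 0.01,
        "BM.HPC.Death.coupling.beta": 6.0,
        "BM.HPC.Death.mod.theta_L": 2.5e5,
        "BM.HPC.Death.mod.h_L": 3.0,
    }
    return ParameterSet(values=v)


def hsc_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    derived = {"BM.HSC.Expn.k", "BM.HPC.Diff.k"}
    out: dict[str, tuple[float, float]] = {}
    for proc in spec.processes:
        for full in proc.param_names():
            leaf = full.rsplit(".", 1)[-1]
            if full in derived or leaf == "h_L":
                continue
            if ".coupling.beta" in full:
                out[full] = _BETA_BOUNDS
            elif ".coupling.inv_theta_L" in full:
                out[full] = _INV_THETA_BOUNDS
            elif ".mod.theta_L" in full:
                out[full] = _THETA_BOUNDS
            else:
                out[full] = _RATE_BOUNDS
    return out


def hsc_stages(spec: ModelSpec):
    bounds = hsc_bounds(spec)
    return [(list(bounds), [(BM, "HSC"), (BM, "HPC")])]


# ---------------------------------------------------------------------------
# G0 sub-model (quiescent/active HSC split, exogenous leukemic-BM forcing)

def g0_spec(g0_reentry: str = "on") -> ModelSpec:
    """Quiescence model.  ``on``: leukemia-stimulated G0 re-entry of active
    HSCs; ``off``: no re-entry process, leukemia-stimulated death of active
    HSCs instead (selective exhaustion of cycling cells)."""
    pops = [(BM, "HSC_G0"), (BM, "HSC_active")]
    procs = [
        ProcessSpec("G0_exit", (BM, "HSC_G0"), (BM, "HSC_active"), "first_order",
                    modifier="suppressive"),
        ProcessSpec("Expn", (BM, "HSC_active"), (BM, "HSC_active"), "first_order",
                    modifier="suppressive"),
        ProcessSpec("Diff", (BM, "HSC_active"), None, "first_order",
                    modifier="suppressive"),
        ProcessSpec("Death", (BM, "HSC_G0"), None, "first_order"),
    ]
    if g0_reentry == "on":
        procs.append(ProcessSpec("G0_reentry", (BM, "HSC_active"), (BM, "HSC_G0"),
                                 "first_order", modifier="stimulative"))
        procs.append(ProcessSpec("Death", (BM, "HSC_active"), None, "first_order"))
        balance = [
            ((BM, "HSC_G0"), "BM.HSC_active.G0_reentry"),
            ((BM, "HSC_active"), "BM.HSC_active.Expn"),
        ]
    elif g0_reentry == "off":
        procs.append(ProcessSpec("Death", (BM, "HSC_active"), None, "first_order",
                                 modifier="stimulative"))
        # without re-entry the quiescent pool has no inflow and cannot be
        # balanced; the active pool is closed through its differentiation
        # outflow, which stays positive for any activation rate
        balance = [((BM, "HSC_active"), "BM.HSC_active.Diff")]
    else:
        raise ValueError(f"g0_reentry must be 'on' or 'off', got {g0_reentry!r}")
    return ModelSpec(populations=pops, processes=procs, hierarchy_level="g0",
                     g0_reentry=g0_reentry, balance=balance, uses_forcing=True,
                     label=f"g0/{g0_reentry}")


def g0_x0(spec: ModelSpec | None = None) -> np.ndarray:
    # 40 % of HSCs quiescent at baseline, total 1e4 cells
    return np.array([4e3, 6e3])


def g0_truth() -> ParameterSet:
    """Generating parameters for the re-entry-on quiescence scenario."""
    v = {
        "BM.HSC_G0.G0_exit.k": 0.9,
        "BM.HSC_G0.G0_exit.coupling.inv_theta_L": 1.0 / 6e5,
        "BM.HSC_G0.G0_exit.mod.h_L": 6.0,
        "BM.HSC_G0.Death.k": 0.005,
        "BM.HSC_active.G0_reentry.k": 0.0,       # derived (G0 balance)
        "BM.HSC_active.G0_reentry.coupling.beta": 2.0,
        "BM.HSC_active.G0_reentry.mod.theta_L": 6e5,
        "BM.HSC_active.G0_reentry.mod.h_L": 6.0,
        "BM.HSC_active.Expn.k": 0.0,             # derived (active balance)
        "BM.HSC_active.Expn.coupling.inv_theta_L": 1.0 / 6e5,
        "BM.HSC_active.Expn.mod.h_L": 6.0,
        "BM.HSC_active.Diff.k": 0.30,
        "BM.HSC_active.Diff.coupling.inv_theta_L": 1.0 / 7.8e5,
        "BM.HSC_active.Diff.mod.h_L": 6.0,
        "BM.HSC_active.Death.k": 0.05,
    }
    return ParameterSet(values=v)


def g0_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    if spec.g0_reentry == "on":
        derived = {"BM.HSC_active.G0_reentry.k", "BM.HSC_active.Expn.k"}
    else:
        derived = {"BM.HSC_active.Diff.k"}
    fixed_leaves = {"h_L"}
    fixed_full = {"BM.HSC_G0.Death.k", "BM.HSC_active.Death.k"} if spec.g0_reentry == "on" \
        else {"BM.HSC_G0.Death.k"}
    out: dict[str, tuple[float, float]] = {}
    for proc in spec.processes:
        for full in proc.param_names():
            leaf = full.rsplit(".", 1)[-1]
            if full in derived or leaf in fixed_leaves or full in fixed_full:
                continue
            if ".coupling.beta" in full:
                out[full] = _BETA_BOUNDS
            elif ".coupling.inv_theta_L" in full:
                out[full] = _INV_THETA_BOUNDS
            elif ".mod.theta_L" in full:
                out[full] = _THETA_BOUNDS
            else:
                out[full] = _RATE_BOUNDS
    return out


def g0_stages(spec: ModelSpec):
    bounds = g0_bounds(spec)
    return [(list(bounds), [(BM, "HSC"), (BM, "HSC_G0")])]


# ---------------------------------------------------------------------------
# fitting templates

#: structural Hill coefficients per process name.  Shape coefficients are
#: constants of the model family — structure choice is handled by discrete
#: enumeration, not by fitting shape exponents — so they are fixed, not free.
_FAMILY_H: dict[str, float] = {
    "SP.leukemic.Prolif": 2.0, "BM.leukemic.Prolif": 2.0, "PB.leukemic.Prolif": 2.0,
    "SP.normal.Prolif": 2.0, "BM.normal.Prolif": 2.0,
    "SP.normal.Death": 3.0, "BM.normal.Export": 3.0,
    "BM.HSC.Expn": 3.0, "BM.HSC.HSC_to_HPC": 3.0,
    "BM.HPC.Diff": 3.0, "BM.HPC.Death": 3.0,
    "BM.HSC_G0.G0_exit": 6.0, "BM.HSC_active.G0_reentry": 6.0,
    "BM.HSC_active.Expn": 6.0, "BM.HSC_active.Diff": 6.0,
    "BM.HSC_active.Death": 6.0,
}

#: fixed (non-fitted) rate constants of the sub-models
_FIXED_VALUES: dict[str, float] = {
    "BM.HSC_G0.Death.k": 0.005,
    "BM.HSC_active.Death.k": 0.05,
}


def _midpoint(lo: float, hi: float) -> float:
    if lo > 0 and hi / lo > 100.0:
        return float(np.sqrt(lo * hi))  # geometric midpoint for scale parameters
    return 0.5 * (lo + hi)


def _build_template(spec: ModelSpec, bounds: dict[str, tuple[float, float]]) -> ParameterSet:
    """Values for every parameter the spec needs: family constants for fixed
    parameters, bound midpoints for free ones, 0 for derived scales."""
    values: dict[str, float] = {}
    for proc in spec.processes:
        for full in proc.param_names():
            leaf = full.rsplit(".", 1)[-1]
            if full in bounds:
                if proc.form_kind == "zero_order":
                    # constant fluxes start at zero so the homeostatic closure
                    # stays feasible whatever the other template values are
                    values[full] = bounds[full][0]
                else:
                    values[full] = _midpoint(*bounds[full])
            elif leaf == "h_L":
                values[full] = _FAMILY_H.get(proc.name, 2.0)
            elif full in _FIXED_VALUES:
                values[full] = _FIXED_VALUES[full]
            else:
                values[full] = 0.0  # derived by the homeostatic closure
    return ParameterSet(values=values, bounds=dict(bounds))


def tissue_template(spec: ModelSpec) -> ParameterSet:
    return _build_template(spec, tissue_bounds(spec))


def hsc_template(spec: ModelSpec) -> ParameterSet:
    return _build_template(spec, hsc_bounds(spec))


def g0_template(spec: ModelSpec) -> ParameterSet:
    return _build_template(spec, g0_bounds(spec))
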