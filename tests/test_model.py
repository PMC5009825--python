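"""Model assembly: rhs construction, enumeration, control reduction, closure."""

import numpy as np
import pytest

from hemakin.model import (
    BalanceError, ConfigurationError, ModelSpec, ParameterSet, ProcessSpec,
    apply_balance, build_rhs, compile_model, control_state, enumerate_structures,
    reduce_to_control, state_vector, subsystem, validate_spec,
)
from hemakin import presets
from hemakin.simulate import OBS_DAYS, observe, simulate


def single_pool(form="first_order", kind="Death"):
    spec = ModelSpec(
        populations=[("BM", "normal")],
        processes=[ProcessSpec(kind, ("BM", "normal"),
                               ("BM", "normal") if kind == "Prolif" else None, form)],
    )
    return spec


def test_single_loss_term_rhs():
    spec = single_pool()
    params = ParameterSet(values={"BM.normal.Death.k": 0.3})
    rhs = build_rhs(spec, params)
    assert rhs(0.0, np.array([100.0]))[0] == pytest.approx(-30.0)


def test_exact_balance_gives_zero_rhs():
    spec = ModelSpec(
        populations=[("BM", "normal")],
        processes=[
            ProcessSpec("Prolif", ("BM", "normal"), ("BM", "normal"), "first_order"),
            ProcessSpec("Death", ("BM", "normal"), None, "first_order"),
        ],
    )
    params = ParameterSet(values={"BM.normal.Prolif.k": 0.25, "BM.normal.Death.k": 0.25})
    rhs = build_rhs(spec, params)
    assert rhs(0.0, np.array([1234.5]))[0] == pytest.approx(0.0, abs=1e-12)


def test_pure_migration_conserves_mass():
    spec = ModelSpec(
        populations=[("SP", "normal"), ("PB", "normal")],
        processes=[ProcessSpec("Export", ("SP", "normal"), ("PB", "normal"),
                               "first_order")],
    )
    params = ParameterSet(values={"SP.normal.Export.k": 0.4})
    rhs = build_rhs(spec, params)
    dx = rhs(0.0, np.array([80.0, 20.0]))
    assert dx.sum() == pytest.approx(0.0, abs=1e-12)
    assert dx[0] == pytest.approx(-32.0)


def test_mobility_cancels_in_population_total(tissue_spec, tissue_truth, tissue_x0):
    """Summed over compartments, migration vanishes: only proliferation and
    death move the whole-body normal count."""
    cm = compile_model(tissue_spec, tissue_truth)
    rng = np.random.default_rng(42)
    for _ in range(10):
        x = rng.uniform(1e2, 1e6, size=len(tissue_spec.populations))
        contrib = cm.signed_contributions(0.0, x)
        normal_idx = [i for i, (_c, p) in enumerate(tissue_spec.populations)
                      if p == "normal"]
        total = contrib[:, normal_idx].sum()
        expected = 0.0
        for pi, proc in enumerate(tissue_spec.processes):
            if proc.home[1] != "normal":
                continue
            if proc.kind == "Prolif":
                expected += contrib[pi, normal_idx].sum()
            elif proc.kind == "Death":
                expected += contrib[pi, normal_idx].sum()
        assert total == pytest.approx(expected, rel=1e-12)


def test_kernel_matches_python_reference(tissue_spec, tissue_truth):
    cm = compile_model(tissue_spec, tissue_truth)
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.uniform(0, 2e6, size=len(tissue_spec.populations))
        np.testing.assert_allclose(cm.rhs(3.7, x), cm.rhs_py(3.7, x),
                                   rtol=1e-13, atol=1e-9)


def test_missing_parameter_named_in_error():
    spec = single_pool()
    with pytest.raises(ConfigurationError, match="BM.normal.Death.k"):
        build_rhs(spec, ParameterSet(values={}))


def test_enumerate_structures_cartesian_product():
    spec = ModelSpec(
        populations=[("BM", "normal")],
        processes=[
            ProcessSpec("Prolif", ("BM", "normal"), ("BM", "normal"), "first_order"),
            ProcessSpec("Death", ("BM", "normal"), None, "first_order"),
        ],
    )
    cands = {"BM.normal.Prolif": ["first_order", "hill", "michaelis_menten"],
             "BM.normal.Death": ["first_order", "exponential_saturating", "zero_order"]}
    pool = enumerate_structures(spec, cands, cap=100)
    assert len(pool) == 9
    # deterministic order: lexicographic by process name, then form kind
    combos = [(s.process("BM.normal.Death").form_kind,
               s.process("BM.normal.Prolif").form_kind) for s in pool]
    assert len(set(combos)) == 9
    assert combos == sorted(combos)

    capped = enumerate_structures(spec, cands, cap=4)
    assert [(s.process("BM.normal.Death").form_kind,
             s.process("BM.normal.Prolif").form_kind) for s in capped] == combos[:4]

    ident = enumerate_structures(spec, {"BM.normal.Death": ["first_order"]}, cap=10)
    assert len(ident) == 1
    assert ident[0].process("BM.normal.Death").form_kind == "first_order"

    with pytest.raises(ConfigurationError):
        enumerate_structures(spec, {"BM.normal.Death": []})


def test_reduce_to_control_zeroes_leukemia(tissue_spec, tissue_truth, tissue_x0):
    spec_c, params_c, x0_c = reduce_to_control(tissue_spec, tissue_truth, tissue_x0)
    for name, v in params_c.values.items():
        if ".coupling." in name:
            assert v == 0.0
        else:
            assert v == tissue_truth[name]  # bit-identical
    traj = simulate(spec_c, params_c, x0_c, span=(0, 21), obs_days=OBS_DAYS)
    for comp in ("PB", "SP", "BM"):
        assert np.all(traj.series((comp, "leukemic")) == 0.0)
        normal = traj.series((comp, "normal"))
        np.testing.assert_allclose(normal, normal[0], rtol=1e-9)

    # idempotence
    _s2, params_c2, x0_c2 = reduce_to_control(spec_c, params_c, x0_c)
    assert params_c2.values == params_c.values
    np.testing.assert_array_equal(x0_c2, x0_c)


def test_control_reduction_equals_modifier_free_model(tissue_spec, tissue_truth, tissue_x0):
    """Purging couplings reproduces a spec built without modifiers."""
    _s, params_c, x0_c = reduce_to_control(tissue_spec, tissue_truth, tissue_x0)
    stripped = tissue_spec.copy()
    stripped.processes = [
        ProcessSpec(p.kind, p.source, p.sink, p.form_kind, modifier="none",
                    driver=p.driver, name=p.name)
        for p in tissue_spec.processes
    ]
    params_plain = ParameterSet(values={
        n: v for n, v in params_c.values.items()
        if ".coupling." not in n and ".mod." not in n
    })
    t1 = simulate(tissue_spec, params_c, x0_c, span=(0, 21), obs_days=OBS_DAYS)
    t2 = simulate(stripped, params_plain, x0_c, span=(0, 21), obs_days=OBS_DAYS)
    np.testing.assert_allclose(t1.at(OBS_DAYS), t2.at(OBS_DAYS), rtol=1e-10, atol=1e-10)


def test_validate_spec_flags_violations():
    bad = ModelSpec(
        populations=[("PB", "normal"), ("SP", "normal"), ("BM", "normal")],
        processes=[
            ProcessSpec("Prolif", ("PB", "normal"), ("PB", "normal"), "first_order"),
            ProcessSpec("Export", ("SP", "normal"), ("BM", "normal"), "first_order"),
        ],
    )
    findings = validate_spec(bad)
    assert any("PB normal proliferation" in f for f in findings)
    assert any("via PB" in f for f in findings)


@pytest.mark.parametrize("builder", [
    lambda: presets.tissue_spec("pb_coupled"),
    lambda: presets.tissue_spec("constant"),
    lambda: presets.tissue_spec("zero"),
    presets.hsc_spec,
    lambda: presets.g0_spec("on"),
    lambda: presets.g0_spec("off"),
])
def test_shipped_specs_validate_clean(builder):
    assert validate_spec(builder()) == []


def test_leukemic_subsystem_is_dynamically_exact(tissue_spec, tissue_truth):
    leuk = [(c, "leukemic") for c in ("PB", "SP", "BM")]
    sub = subsystem(tissue_spec, leuk)
    cm_full = compile_model(tissue_spec, tissue_truth)
    cm_sub = compile_model(sub, tissue_truth)
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.uniform(1e2, 1e6, size=6)
        full = cm_full.rhs(0.0, x)
        idx = [tissue_spec.populations.index(k) for k in leuk]
        np.testing.assert_allclose(cm_sub.rhs(0.0, x[idx]), full[idx], rtol=1e-12)


def test_homeostatic_closure_balances_normal_pools(tissue_spec, tissue_x0):
    params = apply_balance(tissue_spec, presets.tissue_truth(), tissue_x0)
    rhs = build_rhs(tissue_spec, params)
    x_ctrl = control_state(tissue_spec, tissue_x0)
    dx = rhs(0.0, x_ctrl)
    for i, (_c, pop) in enumerate(tissue_spec.populations):
        if pop == "normal":
            assert dx[i] == pytest.approx(0.0, abs=1e-9 * x_ctrl[i])


def test_infeasible_closure_raises():
    spec = ModelSpec(
        populations=[("PB", "normal")],
        processes=[
            ProcessSpec("Death", ("PB", "normal"), None, "first_order"),
            ProcessSpec("Export", ("PB", "normal"), None, "first_order"),
        ],
        balance=[(("PB", "normal"), "PB.normal.Death")],
    )
    # a pool with losses and no inflow would need a negative death rate
    with pytest.raises(BalanceError):
        apply_balance(spec, ParameterSet(values={"PB.normal.Death.k": 0.1,
                                                 "PB.normal.Export.k": 0.2}),
                      np.array([1000.0]))


def test_state_vector_ordering(tissue_spec):
    x = state_vector(tissue_spec, {("BM", "normal"): 5.0, ("PB", "leukemic"): 2.0})
    assert x[tissue_spec.populations.index(("BM", "normal"))] == 5.0
    assert x[tissue_spec.populations.index(("PB", "leukemic"))] == 2.0
    assert x.sum() == 7.0
    with pytest.raises(ConfigurationError):
        state_vector(tissue_spec, {("XX", "normal"): 1.0})
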