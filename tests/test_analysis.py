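"""Decomposition, interval fluxes, factor ranking, and variant comparison."""

import numpy as np
import pytest

from hemakin.analysis import (
    compare_variants, day_intervals, decompose, interval_flux, rank_factors,
)
from hemakin.model import ModelSpec, ParameterSet, ProcessSpec, compile_model
from hemakin.simulate import OBS_DAYS, SolverConfig, simulate


@pytest.fixture(scope="module")
def truth_trajectory(tissue_spec, tissue_truth, tissue_x0):
    return simulate(tissue_spec, tissue_truth, tissue_x0, span=(0, 21),
                    obs_days=OBS_DAYS, solver=SolverConfig(rtol=1e-10, atol=1e-8))


def test_decomposition_signed_sum_equals_rhs(tissue_spec, tissue_truth,
                                             truth_trajectory):
    times = np.arange(0.0, 21.01, 0.5)
    dec = decompose(tissue_spec, tissue_truth, truth_trajectory, times)
    cm = compile_model(tissue_spec, tissue_truth)
    states = truth_trajectory.at(times)
    for pop in tissue_spec.populations:
        ssum = dec.signed_sum(pop)
        j = truth_trajectory.index(pop)
        rhs_vals = np.array([cm.rhs(t, states[i])[j] for i, t in enumerate(times)])
        scale = np.max(np.abs(rhs_vals)) + 1e-12
        np.testing.assert_allclose(ssum, rhs_vals, atol=1e-9 * scale)


def test_decomposition_steady_control_sums_to_zero(tissue_spec, tissue_truth,
                                                   tissue_x0):
    from hemakin.model import reduce_to_control

    spec_c, params_c, x0_c = reduce_to_control(tissue_spec, tissue_truth, tissue_x0)
    traj = simulate(spec_c, params_c, x0_c, span=(0, 21), obs_days=OBS_DAYS)
    dec = decompose(spec_c, params_c, traj)
    for comp in ("PB", "SP", "BM"):
        ssum = dec.signed_sum((comp, "normal"))
        scale = dec.rates.max().max()
        np.testing.assert_allclose(ssum, 0.0, atol=1e-8 * scale)


def test_interval_flux_constant_rate_and_zero_rate():
    spec = ModelSpec(
        populations=[("BM", "normal")],
        processes=[
            ProcessSpec("Import", None, ("BM", "normal"), "zero_order"),
            ProcessSpec("Death", ("BM", "normal"), None, "first_order"),
        ],
    )
    params = ParameterSet(values={"BM.normal.Import.k": 42.0,
                                  "BM.normal.Death.k": 0.0})
    traj = simulate(spec, params, np.array([100.0]), span=(0, 5))
    ft = interval_flux(spec, params, traj, "BM.normal.Import",
                       [(0, 1), (1, 2), (2, 3)])
    np.testing.assert_allclose(ft.flux, 42.0, rtol=1e-9)
    ft0 = interval_flux(spec, params, traj, "BM.normal.Death", [(0, 2), (2, 5)])
    np.testing.assert_allclose(ft0.flux, 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        interval_flux(spec, params, traj, "nope", [(0, 1)])


def test_interval_flux_additive(tissue_spec, tissue_truth, truth_trajectory):
    proc = "BM.normal.Export"
    whole = interval_flux(tissue_spec, tissue_truth, truth_trajectory, proc,
                          [(2.0, 8.0)]).flux[0]
    parts = interval_flux(tissue_spec, tissue_truth, truth_trajectory, proc,
                          [(2.0, 5.0), (5.0, 8.0)]).flux
    assert parts.sum() == pytest.approx(whole, rel=1e-8)


def test_day_intervals_shape():
    iv = day_intervals(21)
    assert len(iv) == 21
    assert iv[0] == (0.0, 1.0) and iv[-1] == (20.0, 21.0)


def test_rank_factors_orders_by_mean_rate(tissue_spec, tissue_truth,
                                          truth_trajectory):
    dec = decompose(tissue_spec, tissue_truth, truth_trajectory)
    rk = rank_factors(dec, ("BM", "normal"), window=(0.0, 21.0))
    tbl = rk.table
    assert list(tbl["rank"]) == list(range(1, len(tbl) + 1))
    assert tbl["mean_abs_rate"].is_monotonic_decreasing
    with pytest.raises(ValueError):
        rank_factors(dec, ("BM", "normal"), window=(30.0, 31.0))


def test_rank_factors_tie_broken_lexicographically():
    spec = ModelSpec(
        populations=[("BM", "normal")],
        processes=[
            ProcessSpec("Death", ("BM", "normal"), None, "first_order",
                        name="BM.normal.B_second"),
            ProcessSpec("Death", ("BM", "normal"), None, "first_order",
                        name="BM.normal.A_first"),
        ],
    )
    params = ParameterSet(values={"BM.normal.B_second.k": 0.1,
                                  "BM.normal.A_first.k": 0.1})
    traj = simulate(spec, params, np.array([100.0]), span=(0, 5))
    dec = decompose(spec, params, traj)
    tbl = rank_factors(dec, ("BM", "normal")).table
    assert list(tbl["process"]) == ["BM.normal.A_first", "BM.normal.B_second"]


def test_compare_variants_matches_manual_welch():
    a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
    res = compare_variants(a, b, alternative="a_lower")
    # independent hand computation of the one-sided Welch statistic
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
    t = (ma - mb) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    from scipy.stats import t as tdist

    p = tdist.cdf(t, df)
    assert res.t == pytest.approx(t, rel=1e-12)
    assert res.p == pytest.approx(p, rel=1e-12)
    assert res.winner == "A"


def test_compare_variants_symmetries():
    a, b = [1.0, 2.0, 4.0, 5.5], [2.0, 3.0, 6.0, 7.0]
    r1 = compare_variants(a, b, alternative="a_lower")
    r2 = compare_variants(b, a, alternative="a_lower", label_a="B", label_b="A")
    assert r1.p == pytest.approx(1.0 - r2.p, rel=1e-12)
    same = compare_variants(a, a, alternative="a_lower")
    assert same.t == pytest.approx(0.0, abs=1e-12)
    assert same.p == pytest.approx(0.5, rel=1e-12)
    assert same.winner == "inconclusive"


def test_compare_variants_degenerate_flagged():
    res = compare_variants([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.degenerate and res.p == 0.5 and res.winner == "inconclusive"
    with pytest.raises(ValueError):
        compare_variants([1.0], [1.0, 2.0])


def test_selection_false_positive_rate_calibrated():
    """Null calibration: with no true difference, the one-tailed test rejects
    at alpha = 0.05 in roughly a twentieth of repetitions (loose <= 10/50)."""
    rng = np.random.default_rng(99)
    rejections = 0
    for _ in range(50):
        a = rng.normal(1.0, 0.2, size=10)
        b = rng.normal(1.0, 0.2, size=10)
        res = compare_variants(a, b, alternative="a_lower", alpha=0.05)
        if res.p < 0.05:
            rejections += 1
    assert rejections <= 10
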