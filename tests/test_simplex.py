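"""Revised primal simplex: oracle agreement, EXPAND, certification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import enumerate_optimum, random_box_lp
from dqq.arith import DOUBLE, QUAD
from dqq.linalg import AT_LOWER, AT_UPPER, BASIC
from dqq.problem import LPProblem, SparseMatrix, to_computational_form
from dqq.simplex import (SolverOptions, compute_infeasibilities,
                         expand_ratio_test, primal_simplex)
from dqq.synthgen import beale_cycling_lp

DOUBLE_OPTS = SolverOptions(feasibility_tol=1e-7, optimality_tol=1e-7,
                            expand_frequency=100000, lu_factor_tol=1.9,
                            lu_update_tol=1.9)
QUAD_OPTS = SolverOptions(feasibility_tol=1e-15, optimality_tol=1e-15,
                          expand_frequency=100000, lu_factor_tol=10.0,
                          lu_update_tol=10.0, ctx=QUAD)


def test_simple_assignment_lp(tiny_lp):
    res = primal_simplex(to_computational_form(tiny_lp), DOUBLE_OPTS)
    assert res.status == "optimal"
    assert res.objective == pytest.approx(-1.0)
    assert float(res.Pinf) == 0.0 and float(res.Dinf) == 0.0


@pytest.mark.parametrize("seed", range(25))
def test_matches_enumeration_oracle_double(seed):
    p = random_box_lp(seed)
    oracle = enumerate_optimum(p)
    res = primal_simplex(to_computational_form(p), DOUBLE_OPTS)
    if oracle is None:
        assert res.status == "infeasible"
    else:
        assert res.status == "optimal"
        assert abs(res.objective - oracle) <= 1e-9 * (1 + abs(oracle))


@pytest.mark.parametrize("seed", range(8))
def test_matches_enumeration_oracle_quad(seed):
    p = random_box_lp(seed)
    oracle = enumerate_optimum(p)
    res = primal_simplex(to_computational_form(p), QUAD_OPTS)
    if oracle is None:
        assert res.status == "infeasible"
    else:
        assert res.status == "optimal"
        # oracle is float-precision; the integer-data optimum is exact there
        assert abs(res.objective - oracle) <= 1e-12 * (1 + abs(oracle))
        assert float(res.Dinf) <= 1e-15 * (1 + float(np.max(np.abs(
            np.asarray(res.y, dtype=float)))))


def test_unbounded_returns_ray_certificate():
    p = LPProblem(SparseMatrix.from_dense([[1.0, -1.0]]), ["E"],
                  np.array([0.0]), np.array([-1.0, 0.0]), np.zeros(2),
                  np.full(2, np.inf))
    res = primal_simplex(to_computational_form(p), DOUBLE_OPTS)
    assert res.status == "unbounded"
    assert res.ray is not None
    # the ray is a feasible direction with negative cost
    ray = np.asarray(res.ray[:2], dtype=float)
    assert ray @ np.array([1.0, -1.0]) == pytest.approx(0.0, abs=1e-9)
    assert ray @ p.c < 0


def test_beale_terminates_under_expand_but_cycles_classically():
    """The classic cycling LP: EXPAND's positive step floor breaks the cycle
    that the textbook minimum-ratio rule falls into."""
    p = beale_cycling_lp()
    form = to_computational_form(p)
    res = primal_simplex(form, DOUBLE_OPTS)
    assert res.status == "optimal"
    assert res.objective == pytest.approx(-0.05, abs=1e-9)

    from dataclasses import replace
    classic = replace(DOUBLE_OPTS, classic_ratio_test=True,
                      iteration_limit=300)
    res2 = primal_simplex(form, classic)
    assert res2.status == "iteration_limit"     # stalls/cycles forever
    assert res2.objective == pytest.approx(0.0)  # ... with zero progress


def test_expand_ratio_test_prefers_largest_pivot_on_ties():
    # two exactly tied ratios with pivots 0.1 and 10 -> the 10 leaves
    delta = np.array([-0.1, -10.0])
    x_B = np.array([1.0, 100.0])
    lo_B = np.array([0.0, 0.0])
    hi_B = np.array([np.inf, np.inf])
    kind, pos, step, bound = expand_ratio_test(
        delta, x_B, lo_B, hi_B, np.inf, 1e-7, 1e-12, 1e-11)
    assert kind == "pivot" and pos == 1 and bound == "lower"
    assert step == pytest.approx(10.0)


def test_expand_ratio_test_nondegenerate_classic_ratio():
    delta = np.array([-2.0, -1.0])
    x_B = np.array([4.0, 10.0])
    lo_B = np.array([0.0, 0.0])
    hi_B = np.array([np.inf, np.inf])
    kind, pos, step, bound = expand_ratio_test(
        delta, x_B, lo_B, hi_B, np.inf, 1e-7, 1e-12, 1e-11)
    assert kind == "pivot" and pos == 0
    assert step == pytest.approx(2.0)


def test_expand_gives_positive_step_at_degenerate_vertex():
    # basic variable exactly at its bound: classic ratio is 0, EXPAND floors
    delta = np.array([-1.0])
    x_B = np.array([0.0])
    lo_B = np.array([0.0])
    hi_B = np.array([np.inf])
    inc = 5e-13
    kind, pos, step, bound = expand_ratio_test(
        delta, x_B, lo_B, hi_B, np.inf, 1e-7, inc, 1e-11)
    assert kind == "pivot"
    assert float(step) >= inc      # positive step despite zero ratio


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 9))
def test_expand_step_respects_expanded_bounds(seed):
    """Property: the chosen step never pushes any basic variable beyond its
    blocking bound by more than the post-iteration working tolerance, and
    the step is nonnegative."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 8))
    delta = rng.standard_normal(m)
    lo_B = rng.uniform(-2, 0, m)
    hi_B = lo_B + rng.uniform(0, 3, m)
    x_B = np.clip(rng.uniform(-2.2, 3.2, m), lo_B, hi_B)
    tol_work, inc = 1e-7, 1e-12
    kind, pos, step, bound = expand_ratio_test(
        delta, x_B, lo_B, hi_B, np.inf, tol_work, inc, 1e-11)
    if kind == "unbounded":
        return
    assert kind == "pivot" and step >= 0
    x_new = x_B + delta * step
    tol_new = (tol_work + inc) * (1 + np.maximum(np.abs(lo_B), np.abs(hi_B)))
    assert np.all(x_new >= lo_B - tol_new - 1e-15)
    assert np.all(x_new <= hi_B + tol_new + 1e-15)


def test_compute_infeasibilities_trivial_and_perturbed():
    p = LPProblem(SparseMatrix(0, 1), [], np.zeros(0), np.array([1.0]),
                  np.array([2.0]), np.array([3.0]))
    form = to_computational_form(p)
    st = np.array([AT_LOWER], dtype=np.int8)
    pinf, dinf = compute_infeasibilities(form, [2.0], [], st)
    assert float(pinf) == 0.0 and float(dinf) == 0.0
    pinf, dinf = compute_infeasibilities(form, [3.0 + 1e-6], [], st)
    assert float(pinf) == pytest.approx(1e-6, rel=1e-12)


def test_reported_infeasibilities_match_recomputation():
    p = random_box_lp(5)
    form = to_computational_form(p)
    res = primal_simplex(form, DOUBLE_OPTS)
    pinf, dinf = compute_infeasibilities(form, res.v, res.y,
                                         res.basis.statuses)
    assert float(res.Pinf) == float(pinf)
    assert float(res.Dinf) == float(dinf)


@pytest.mark.parametrize("seed", range(6))
def test_weak_duality_at_reported_optimum(seed):
    """|c^T v - (y^T b + bound terms)| is bounded by the certified
    infeasibilities: the dual objective rebuilt from (y, z) matches."""
    p = random_box_lp(seed, m=3, n=5)
    form = to_computational_form(p)
    res = primal_simplex(form, DOUBLE_OPTS)
    if res.status != "optimal":
        pytest.skip("infeasible draw")
    x = np.asarray(res.v, dtype=float)
    y = np.asarray(res.y, dtype=float)
    z = np.asarray(res.z, dtype=float)
    # dual objective: y^T b + sum_j z_j * (active bound of j)
    dual = y @ form.b
    for j in range(form.n_total):
        st = res.basis.statuses[j]
        if st == AT_LOWER:
            dual += z[j] * form.lower[j]
        elif st == AT_UPPER:
            dual += z[j] * form.upper[j]
    primal = form.c @ x
    gap = abs(primal - dual)
    bound = 10 * max(float(res.Pinf) * (1 + np.abs(form.c).max()),
                     float(res.Dinf) * (1 + np.abs(x).max()), 1e-9)
    assert gap <= bound


def test_warm_start_from_optimal_basis_takes_no_pivots():
    p = random_box_lp(2, m=5, n=8)
    form = to_computational_form(p)
    first = primal_simplex(form, DOUBLE_OPTS)
    assert first.status == "optimal"
    again = primal_simplex(form, DOUBLE_OPTS, start=first.basis)
    assert again.status == "optimal"
    assert again.iterations == 0
    second = primal_simplex(form, QUAD_OPTS, start=first.basis)
    assert second.status == "optimal"
    assert abs(second.objective - first.objective) <= 1e-7 * (
        1 + abs(first.objective))


def test_bound_flip_handles_boxed_variables():
    # min -x1 with x1 in [0, 1] free of any constraint rows: optimum at the
    # flip of x1 to its upper bound
    p = LPProblem(SparseMatrix(0, 1), [], np.zeros(0), np.array([-1.0]),
                  np.zeros(1), np.ones(1))
    res = primal_simplex(to_computational_form(p), DOUBLE_OPTS)
    assert res.status == "optimal" and res.objective == pytest.approx(-1.0)
    assert res.basis.statuses[0] == AT_UPPER
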