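"""Coupling constraints, lifting, consistency, FVA, growth bisection."""

import numpy as np
import pytest

from conftest import enumerate_optimum
from dqq.arith import QUAD
from dqq.cobra_ext import (CouplingSpec, add_coupling_constraints,
                           consistency_check, flux_variability,
                           lift_large_coefficients, max_growth_bisection)
from dqq.driver import run_dqq
from dqq.problem import (LPProblem, SparseMatrix, to_computational_form,
                         with_extra_rows)
from dqq.simplex import SolverOptions, primal_simplex

FAST = SolverOptions(feasibility_tol=1e-9, optimality_tol=1e-9,
                     expand_frequency=100000, lu_factor_tol=5.0,
                     lu_update_tol=5.0)


def box_lp(n, c, lo=0.0, hi=5.0, sense="min"):
    return LPProblem(SparseMatrix(0, n), [], np.zeros(0), np.asarray(c,
                     dtype=float), np.full(n, lo), np.full(n, hi),
                     sense=sense)


# -- coupling ---------------------------------------------------------------

def test_equal_coupling_forces_flux_equality():
    p = box_lp(2, [-1.0, 0.0])
    q = add_coupling_constraints(p, CouplingSpec([(0, 1, 1.0, 1.0)]))
    assert q.m == 2                      # both rows present for c_min = c_max
    res = primal_simplex(to_computational_form(q), FAST)
    assert res.status == "optimal"
    assert float(res.v[0]) == pytest.approx(float(res.v[1]), abs=1e-9)
    assert float(res.v[0]) == pytest.approx(5.0)


def test_zero_lower_coupling_adds_single_row():
    p = box_lp(2, [0.0, 0.0])
    q = add_coupling_constraints(p, CouplingSpec([(0, 1, 0.0, 10.0)]))
    assert q.m == 1
    assert q.S.get(0, 0) == 1.0 and q.S.get(0, 1) == -10.0


def test_coupling_validation_errors():
    p = box_lp(2, [0.0, 0.0])
    with pytest.raises(ValueError, match="c_min"):
        add_coupling_constraints(p, CouplingSpec([(0, 1, 2.0, 1.0)]))
    p2 = box_lp(2, [0.0, 0.0], lo=-1.0)
    with pytest.raises(ValueError, match="nonnegative"):
        add_coupling_constraints(p2, CouplingSpec([(0, 1, 0.0, 1.0)]))


def test_coupled_feasible_region_matches_halfplane_oracle():
    """3-flux toy with ratio bounds [0.5, 2]: optimal vertices of several
    objectives match the hand-enumerated polygon intersection."""
    p = box_lp(3, [0.0, 0.0, 0.0], hi=4.0)
    q = add_coupling_constraints(p, CouplingSpec([(0, 1, 0.5, 2.0)]))
    for c, expected in [
        ([-1.0, 0.0, 0.0], -4.0),       # max v0: v0 = 4 (v1 = 2 suffices)
        ([-1.0, 1.0, 0.0], -2.0),       # max v0 - v1: v0 = 4, v1 = v0/2 = 2
        ([1.0, -1.0, 0.0], -2.0),       # max v1 - v0: v1 = 4, v0 = v1/2 = 2
        ([0.0, 0.0, -1.0], -4.0),       # v2 uncoupled
    ]:
        q2 = q.copy()
        q2.c = np.array(c)
        res = primal_simplex(to_computational_form(q2), FAST)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(expected, abs=1e-9)


# -- lifting ----------------------------------------------------------------

def test_lifting_splits_large_entry_once():
    S = SparseMatrix.from_dense([[8.0e5, 1.0]])
    p = LPProblem(S, ["E"], np.array([8.0e5]), np.array([1.0, 1.0]),
                  np.zeros(2), np.full(2, 10.0))
    q = lift_large_coefficients(p, 1e4)
    assert q.S.max_abs() <= 1e4
    assert q.m == p.m + 1 and q.n == p.n + 1     # one pass suffices
    assert q.S.max_abs() == pytest.approx(np.sqrt(8.0e5))


def test_lifting_identity_when_all_small():
    p = box_lp(2, [1.0, 1.0])
    q = lift_large_coefficients(p, 10.0)
    assert q.m == p.m and q.n == p.n


def test_lifting_recursive_for_huge_entries():
    S = SparseMatrix.from_dense([[1.0e8, -1.0]])
    p = LPProblem(S, ["E"], np.array([0.0]), np.array([0.0, -1.0]),
                  np.zeros(2), np.array([1.0, np.inf]))
    q = lift_large_coefficients(p, 1e3)
    assert q.S.max_abs() <= 1e3
    rep_orig = run_dqq(p)
    rep_lift = run_dqq(q)
    assert rep_orig.status == rep_lift.status == "optimal"
    assert abs(rep_lift.objective - rep_orig.objective) <= \
        1e-20 * (1 + abs(rep_orig.objective))


def test_lifting_rejects_tau_below_one():
    with pytest.raises(ValueError):
        lift_large_coefficients(box_lp(1, [1.0]), 0.5)


# -- stoichiometric consistency --------------------------------------------

def test_consistent_two_species_reaction():
    # A -> B: masses (1, 1) satisfy S^T ell = 0
    S = SparseMatrix.from_dense(np.array([[1.0], [-1.0]]))
    ell, flagged = consistency_check(S, opts=FAST)
    assert not flagged
    assert np.all(ell >= 1e-4 * (1 - 1e-9))


def test_creation_from_nothing_is_flagged():
    # A appears from nowhere: S^T ell = 0 forces ell_A = 0
    S = SparseMatrix.from_dense(np.array([[1.0], [0.0]]))
    ell, flagged = consistency_check(S, opts=FAST)
    assert 0 in flagged and 1 not in flagged


def test_unbalanced_row_flag_matches_bruteforce():
    """4 species, one unbalanced: the flag set matches exhaustive search for
    a strictly positive mass vector over sign patterns."""
    # reactions: A -> B, B -> C, and the leak C -> (nothing)
    M = np.array([
        [-1.0, 0.0, 0.0],
        [1.0, -1.0, 0.0],
        [0.0, 1.0, -1.0],
        [0.0, 0.0, 0.0],
    ])
    S = SparseMatrix.from_dense(M)
    ell, flagged = consistency_check(S, opts=FAST)
    # brute force: ell > 0 with M^T ell = 0 needs ell_A=ell_B=ell_C and
    # then row 3 (C -> nothing) forces ell_C = 0: species A, B, C flagged;
    # species D (row 4) is isolated and free to carry any mass
    assert flagged == {0, 1, 2}
    assert ell[3] >= 1e-4 * (1 - 1e-9)


def test_alpha_beta_validation():
    with pytest.raises(ValueError):
        consistency_check(SparseMatrix.from_dense([[1.0]]), alpha=1.0,
                          beta=0.5)


# -- FVA --------------------------------------------------------------------

def test_fva_box_only_recovers_bounds():
    p = box_lp(3, [0.0, 0.0, 0.0], lo=1.0, hi=4.0)
    res = flux_variability(p, gamma=1.0, opts=FAST, Z0=0.0)
    assert np.allclose(res.minima, 1.0) and np.allclose(res.maxima, 4.0)


def test_fva_loop_flux_fixed_by_gamma_one():
    # A <-> B loop: v1 - v2 = 0, maximize v1 with gamma = 1 pins both at 5
    S = SparseMatrix.from_dense([[1.0, -1.0]])
    p = LPProblem(S, ["E"], np.array([0.0]), np.array([1.0, 0.0]),
                  np.zeros(2), np.full(2, 5.0), sense="max")
    res = flux_variability(p, gamma=1.0, opts=FAST)
    assert res.Z0 == pytest.approx(5.0)
    assert np.allclose(res.minima, 5.0, atol=1e-8)
    assert np.allclose(res.maxima, 5.0, atol=1e-8)


def test_fva_interval_widths_monotone_in_gamma_and_contain_optimum():
    rng = np.random.default_rng(17)
    M = rng.integers(-2, 3, size=(3, 5)).astype(float)
    x_ref = rng.uniform(1, 2, size=5)
    p = LPProblem(SparseMatrix.from_dense(M), ["E"] * 3, M @ x_ref,
                  rng.integers(1, 4, size=5).astype(float),
                  np.zeros(5), np.full(5, 4.0), sense="max")
    base = primal_simplex(to_computational_form(p), FAST)
    assert base.status == "optimal"
    vstar = np.array([float(v) for v in base.v[:5]])
    prev_width = None
    for gamma in (1.0, 0.9, 0.5):
        res = flux_variability(p, gamma=gamma, opts=FAST)
        widths = res.maxima - res.minima
        assert np.all(res.minima <= vstar + 1e-7)
        assert np.all(res.maxima >= vstar - 1e-7)
        if prev_width is not None:
            assert np.all(widths >= prev_width - 1e-9)
        prev_width = widths


def test_fva_against_enumeration_oracle():
    rng = np.random.default_rng(23)
    M = rng.integers(-2, 3, size=(2, 4)).astype(float)
    x_ref = rng.uniform(1, 2, size=4)
    p = LPProblem(SparseMatrix.from_dense(M), ["E"] * 2, M @ x_ref,
                  np.array([1.0, 2.0, 0.0, 1.0]), np.zeros(4),
                  np.full(4, 4.0), sense="max")
    res = flux_variability(p, gamma=0.9, opts=FAST)
    # oracle: per flux, extremize v_j by enumeration over the constrained LP
    coeffs = {j: float(p.c[j]) for j in range(4) if p.c[j] != 0.0}
    limited = with_extra_rows(p, [(coeffs, "G", 0.9 * res.Z0, "gam")])
    for k, j in enumerate(res.indices):
        for direction, got in (("min", res.minima[k]), ("max", res.maxima[k])):
            q = limited.copy()
            q.c = np.zeros(4)
            q.c[j] = 1.0 if direction == "min" else -1.0
            q.sense = "min"
            oracle = enumerate_optimum(q)
            want = oracle if direction == "min" else -oracle
            assert got == pytest.approx(want, abs=1e-7)


def test_fva_warm_matches_cold():
    rng = np.random.default_rng(29)
    M = rng.integers(-2, 3, size=(3, 6)).astype(float)
    x_ref = rng.uniform(1, 2, size=6)
    p = LPProblem(SparseMatrix.from_dense(M), ["E"] * 3, M @ x_ref,
                  rng.integers(1, 4, size=6).astype(float), np.zeros(6),
                  np.full(6, 4.0), sense="max")
    warm = flux_variability(p, gamma=0.95, opts=FAST, warm=True)
    cold = flux_variability(p, gamma=0.95, opts=FAST, warm=False)
    assert np.allclose(warm.minima, cold.minima, atol=1e-8)
    assert np.allclose(warm.maxima, cold.maxima, atol=1e-8)


# -- growth bisection -------------------------------------------------------

def _demand_builder(k_eff, demand, mu_cap=4.0):
    """v <= (mu/k_eff) w, w <= 1, v >= demand: feasible iff mu >= k_eff*demand."""

    def build(mu):
        p = LPProblem(SparseMatrix(0, 2), [], np.zeros(0), np.zeros(2),
                      np.array([demand, 0.0]), np.array([np.inf, 1.0]),
                      col_names=["use", "syn"])
        return add_coupling_constraints(
            p, CouplingSpec([(0, 1, 0.0, mu / k_eff)]))

    return build


def test_bisection_recovers_planted_threshold():
    out = max_growth_bisection(_demand_builder(2.0, 0.5), 0.1, 4.0,
                               tol_mu=1e-6, opts=FAST)
    assert out["mu_star"] == pytest.approx(1.0, abs=1e-6)


def test_bisection_with_large_rate_constant():
    # k_eff = 234000, demand 1e-6: threshold mu* = 0.234
    out = max_growth_bisection(_demand_builder(234000.0, 1e-6), 0.01, 1.0,
                               tol_mu=1e-6, opts=FAST)
    assert out["mu_star"] == pytest.approx(0.234, abs=1e-6)


def test_bisection_endpoint_validation():
    # threshold 1.0: [1.5, 4] is feasible throughout, [0.1, 0.5] nowhere
    with pytest.raises(ValueError, match="feasible at both"):
        max_growth_bisection(_demand_builder(2.0, 0.5), 1.5, 4.0, opts=FAST)
    with pytest.raises(ValueError, match="infeasible at both"):
        max_growth_bisection(_demand_builder(2.0, 0.5), 0.1, 0.5, opts=FAST)


@pytest.mark.parametrize("seed", range(6))
def test_bisection_solve_count_bound(seed):
    """Recovery within tol in ceil(log2(range/tol)) + 2 endpoint solves."""
    rng = np.random.default_rng(seed)
    k_eff = float(rng.uniform(1.0, 10.0))
    demand = float(rng.uniform(0.05, 0.4))
    mu_lo, mu_hi, tol = 0.01, 8.0, 1e-6
    out = max_growth_bisection(_demand_builder(k_eff, demand), mu_lo, mu_hi,
                               tol_mu=tol, opts=FAST)
    assert out["mu_star"] == pytest.approx(k_eff * demand, abs=tol)
    assert out["solves"] <= int(np.ceil(np.log2((mu_hi - mu_lo) / tol))) + 2
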