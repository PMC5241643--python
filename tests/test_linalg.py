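"""Basis factorization, solves, updates, repair."""

import numpy as np
import pytest

from dqq.arith import DOUBLE, QUAD, extended, inf_norm
from dqq.linalg import (AT_LOWER, BASIC, BasisState, factorize, repair_basis,
                        slack_basis, update_after_pivot)
from dqq.problem import LPProblem, SparseMatrix, to_computational_form


def dense_residual(f, B, ctx):
    """||B - reconstructed||_inf via the factors' own reconstruction."""
    R = f.reconstruct()
    return float(inf_norm(np.asarray(B - R).ravel()))


def test_identity_basis_factorizes_trivially():
    B = DOUBLE.eye(4)
    f = factorize(B, 1.9, DOUBLE)
    assert not f.dependents
    x = f.solve(np.arange(4.0))
    assert np.allclose(x, np.arange(4.0))
    y = f.solve_T(np.arange(4.0))
    assert np.allclose(y, np.arange(4.0))


def test_duplicated_column_reports_one_dependent():
    B = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 1.0], [0.0, 0.0, 3.0]])
    f = factorize(B, 1.9, DOUBLE)
    assert len(f.dependents) == 1


@pytest.mark.parametrize("ctx,tol", [(DOUBLE, 1e-12), (QUAD, 1e-30)])
def test_reconstruction_error_small(ctx, tol):
    rng = np.random.default_rng(7)
    M = rng.standard_normal((8, 8))
    M[rng.random((8, 8)) < 0.4] = 0.0
    M += 3 * np.eye(8)                      # condition ~1e3 at most
    B = ctx.array(M)
    with ctx.workprec():
        f = factorize(B, 10.0, ctx)
        assert not f.dependents
        err = dense_residual(f, B, ctx)
    assert err <= tol * float(inf_norm(M.ravel()))


@pytest.mark.parametrize("ctx", [DOUBLE, QUAD])
def test_solve_recovers_known_vector(ctx):
    rng = np.random.default_rng(3)
    M = rng.standard_normal((6, 6)) + 4 * np.eye(6)
    e = rng.standard_normal(6)
    B = ctx.array(M)
    with ctx.workprec():
        f = factorize(B, 5.0, ctx)
        eh = ctx.array(e)
        x = f.solve(B @ eh)                 # rhs built in ctx precision
        err = float(inf_norm(x - eh))
        y = f.solve_T(B.T @ eh)
        errT = float(inf_norm(y - eh))
    bound = 1e-10 if ctx.is_double else 1e-28
    assert err <= bound and errT <= bound


def test_refinement_reduces_error_on_ill_conditioned_system():
    """One high-precision-residual pass gains >= 10x on a Hilbert system."""
    from fractions import Fraction
    n = 6
    H = np.array([[1.0 / (i + j + 1) for j in range(n)] for i in range(n)])
    rhs = H @ np.ones(n)
    # exact solution of the double-rounded system, via rational elimination
    Hf = [[Fraction(H[i, j]) for j in range(n)] for i in range(n)]
    bf = [Fraction(v) for v in rhs]
    from conftest import _frac_solve
    xstar = np.array([float(v) for v in _frac_solve(Hf, bf)])
    f = factorize(H, 5.0, DOUBLE)
    e0 = float(inf_norm(f.solve(rhs, refine=0) - xstar))
    e1 = float(inf_norm(f.solve(rhs, refine=1) - xstar))
    assert e1 <= e0 / 10


def test_random_solves_match_dense_oracle():
    """Solutions agree with a high-precision dense elimination oracle."""
    rng = np.random.default_rng(12)
    for trial in range(5):
        m = int(rng.integers(3, 12))
        M = rng.standard_normal((m, m)) + (m + 1) * np.eye(m)
        rhs = rng.standard_normal(m)
        f = factorize(M.astype(float), 5.0, DOUBLE)
        x = f.solve(rhs)
        hi = extended(50)
        with hi.workprec():
            xh = np.array([float(v) for v in _dense_solve_hi(hi, M, rhs)])
        assert np.allclose(x, xh, atol=1e-10, rtol=1e-10)


def _dense_solve_hi(hi, M, rhs):
    A = hi.array(M)
    b = hi.array(rhs)
    m = len(b)
    for k in range(m):
        p = max(range(k, m), key=lambda i: abs(A[i, k]))
        if p != k:
            A[[k, p]] = A[[p, k]]
            b[[k, p]] = b[[p, k]]
        for i in range(k + 1, m):
            fct = A[i, k] / A[k, k]
            A[i, k:] = A[i, k:] - fct * A[k, k:]
            b[i] = b[i] - fct * b[k]
    x = hi.zeros(m)
    for k in range(m - 1, -1, -1):
        x[k] = (b[k] - A[k, k + 1:] @ x[k + 1:]) / A[k, k]
    return x


def test_update_sequence_matches_fresh_factorization():
    rng = np.random.default_rng(5)
    m = 5
    B0 = rng.standard_normal((m, m)) + 4 * np.eye(m)
    Bfinal = B0.copy()
    f = factorize(B0.copy(), 5.0, DOUBLE)
    for pos in range(m):
        col = rng.standard_normal(m) + 2 * np.eye(m)[:, pos]
        w = f.solve(col)
        assert update_after_pivot(f, w, pos, 10.0, DOUBLE)
        Bfinal[:, pos] = col
    fresh = factorize(Bfinal, 5.0, DOUBLE)
    rhs = rng.standard_normal(m)
    x_upd = f.solve(rhs)
    x_new = fresh.solve(rhs)
    assert np.allclose(x_upd, x_new, atol=1e-9)
    y_upd = f.solve_T(rhs)
    y_new = fresh.solve_T(rhs)
    assert np.allclose(y_upd, y_new, atol=1e-9)


def test_replacing_column_with_itself_keeps_solves():
    rng = np.random.default_rng(9)
    B = rng.standard_normal((4, 4)) + 3 * np.eye(4)
    f = factorize(B, 5.0, DOUBLE)
    w = f.solve(B[:, 2])
    assert update_after_pivot(f, w, 2, 10.0, DOUBLE)
    rhs = rng.standard_normal(4)
    assert np.allclose(f.solve(rhs), factorize(B, 5.0, DOUBLE).solve(rhs),
                       atol=1e-10)


def test_tiny_update_pivot_signals_refactorization():
    B = np.eye(3)
    f = factorize(B, 5.0, DOUBLE)
    w = np.array([1.0, 1e-14, 0.5])     # replacing col 1: pivot 1e-14
    assert update_after_pivot(f, w, 1, 10.0, DOUBLE) is False
    assert f.update_count == 0


def test_update_count_limit_signals_refactorization():
    B = np.eye(2)
    f = factorize(B, 5.0, DOUBLE, max_updates=1)
    assert update_after_pivot(f, np.array([1.0, 0.5]), 0, 10.0, DOUBLE)
    assert update_after_pivot(f, np.array([1.0, 0.5]), 0, 10.0, DOUBLE) is False


def _toy_form():
    p = LPProblem(SparseMatrix.from_dense(np.eye(3)), ["E"] * 3,
                  np.ones(3), np.zeros(3), np.zeros(3), np.full(3, 2.0))
    return to_computational_form(p)


def test_repair_without_dependents_is_identity():
    form = _toy_form()
    basis = slack_basis(form)
    repaired, log = repair_basis(basis, [], form)
    assert repaired.basic == basis.basic and not log


def test_doubly_deficient_basis_repairs_to_nonsingular():
    """Two duplicated structural columns: repair, then factorize cleanly."""
    M = np.array([[1.0, 1.0, 2.0, 2.0], [0.0, 0.0, 1.0, 1.0],
                  [1.0, 1.0, 0.0, 0.0]])
    p = LPProblem(SparseMatrix.from_dense(M), ["E"] * 3, np.ones(3),
                  np.zeros(4), np.zeros(4), np.full(4, 5.0))
    form = to_computational_form(p)
    A = form.dense_A(DOUBLE)
    basis = BasisState(np.array([0, 0, 0, 0, 1, 1, 1], dtype=np.int8),
                       [0, 1, 2])
    basis.statuses[3] = AT_LOWER
    f = factorize(A[:, basis.basic], 5.0, DOUBLE)
    assert len(f.dependents) >= 1
    repaired, _ = repair_basis(basis, f.dependents, form)
    f2 = factorize(A[:, repaired.basic], 5.0, DOUBLE)
    assert not f2.dependents
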