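"""Shared fixtures and independent oracles.

The main oracle enumerates every basic solution of the computational slack
form (choose m basic columns, fix every nonbasic at one of its finite bounds,
solve the square system) and returns the best feasible objective.  It is a
brute-force check, deliberately independent of the simplex implementation,
and is only used at sizes where the enumeration is exhaustive.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from dqq.arith import DOUBLE
from dqq.problem import LPProblem, SparseMatrix, to_computational_form


def random_box_lp(seed: int, m: int = 4, n: int = 6, int_entries: bool = True,
                  bound_hi: float = 3.0) -> LPProblem:
    """Small random LP: integer entries in {-2..2}, bounds [0, bound_hi]."""
    rng = np.random.default_rng(seed)
    while True:
        M = rng.integers(-2, 3, size=(m, n)).astype(float) if int_entries \
            else np.round(rng.standard_normal((m, n)), 3)
        if np.all(np.any(M != 0, axis=1)):
            break
    senses = [("E", "L", "G")[int(k)] for k in rng.integers(0, 3, size=m)]
    x_ref = rng.uniform(0.5, bound_hi - 0.5, size=n)
    act = M @ x_ref
    # integer data throughout: every vertex is a modest rational, so the
    # enumeration oracle is exact and distinct optima are well separated
    rhs = np.round(act)
    c = rng.integers(-3, 4, size=n).astype(float)
    return LPProblem(SparseMatrix.from_dense(M), senses, rhs, c,
                     np.zeros(n), np.full(n, bound_hi))


def enumerate_optimum(p: LPProblem, tol: float = 1e-9, exact: bool = False):
    """Best objective over all basic solutions; None when infeasible.

    Vectorized over bound assignments: for each basis subset the nonbasic
    block is fixed at every combination of its finite bounds at once.  With
    ``exact=True`` the near-best vertices are re-evaluated in rational
    arithmetic and the exact optimal objective (a Fraction) is returned —
    the reference for quad-precision comparisons.
    """
    form = to_computational_form(p)
    m, nt = form.m, form.n_total
    A = form.dense_A(DOUBLE)
    b = form.b
    lo, hi = form.lower, form.upper
    c = form.c
    best = None
    finalists = []          # (float objective, basic, combo) near the best
    for basic in itertools.combinations(range(nt), m):
        nb = [j for j in range(nt) if j not in basic]
        B = A[:, basic]
        try:
            Binv = np.linalg.inv(B)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(Binv)):
            continue
        # candidate values for each nonbasic: its finite bounds (0 for free)
        choices = []
        for j in nb:
            vals = []
            if np.isfinite(lo[j]):
                vals.append(lo[j])
            if np.isfinite(hi[j]) and hi[j] != lo[j]:
                vals.append(hi[j])
            if not vals:
                vals = [0.0]
            choices.append(vals)
        combos = np.array(list(itertools.product(*choices)))  # (k, |nb|)
        N = A[:, nb]
        xb = Binv @ (b[:, None] - N @ combos.T)               # (m, k)
        ok = np.ones(xb.shape[1], dtype=bool)
        for pos, j in enumerate(basic):
            ok &= (xb[pos] >= lo[j] - tol) & (xb[pos] <= hi[j] + tol)
        if not np.any(ok):
            continue
        obj = c[list(basic)] @ xb[:, ok] + c[nb] @ combos[ok].T
        cand = obj.min()
        if best is None or cand < best:
            best = cand
        if exact:
            for kk in np.nonzero(ok)[0]:
                o = c[list(basic)] @ xb[:, kk] + c[nb] @ combos[kk]
                finalists.append((o, basic, combos[kk], nb))
    if best is None:
        return None
    if not exact:
        return form.sense_sign * best + form.objective_constant
    # rational re-evaluation of every vertex within 1e-6 of the float best
    Af = [[Fraction(A[i, j]) for j in range(nt)] for i in range(m)]
    bf = [Fraction(v) for v in b]
    cf = [Fraction(v) for v in c]
    exact_best = None
    for o, basic, combo, nb in finalists:
        if o > best + 1e-6 * (1 + abs(best)):
            continue
        rhs = [bf[i] - sum(Af[i][j] * Fraction(v)
                           for j, v in zip(nb, combo)) for i in range(m)]
        sol = _frac_solve([[Af[i][j] for j in basic] for i in range(m)], rhs)
        if sol is None:
            continue
        feas = all((not np.isfinite(lo[j]) or sol[pos] >= Fraction(lo[j]))
                   and (not np.isfinite(hi[j]) or sol[pos] <= Fraction(hi[j]))
                   for pos, j in enumerate(basic))
        if not feas:
            continue
        objx = sum(cf[j] * Fraction(v) for j, v in zip(nb, combo)) + \
            sum(cf[j] * sol[pos] for pos, j in enumerate(basic))
        if exact_best is None or objx < exact_best:
            exact_best = objx
    if exact_best is None:
        return form.sense_sign * best + form.objective_constant
    return (Fraction(form.sense_sign) * exact_best
            + Fraction(form.objective_constant))


def exact_vertex_optimum(p: LPProblem):
    """Same enumeration in exact rational arithmetic (tiny instances only).

    Returns (objective, x, y, statuses) of the best basic feasible solution,
    with y the exact duals of its basis, or None when infeasible.
    """
    form = to_computational_form(p)
    m, nt = form.m, form.n_total
    Af = form.dense_A(DOUBLE)
    A = [[Fraction(Af[i, j]) for j in range(nt)] for i in range(m)]
    b = [Fraction(x) for x in form.b]
    lo, hi = form.lower, form.upper
    c = [Fraction(x) for x in form.c]
    best = None
    for basic in itertools.combinations(range(nt), m):
        nb = [j for j in range(nt) if j not in basic]
        choices = []
        for j in nb:
            vals = []
            if np.isfinite(lo[j]):
                vals.append(Fraction(lo[j]))
            if np.isfinite(hi[j]) and hi[j] != lo[j]:
                vals.append(Fraction(hi[j]))
            if not vals:
                vals = [Fraction(0)]
            choices.append(vals)
        for combo in itertools.product(*choices):
            rhs = [b[i] - sum(A[i][j] * v for j, v in zip(nb, combo))
                   for i in range(m)]
            sol = _frac_solve([[A[i][j] for j in basic] for i in range(m)], rhs)
            if sol is None:
                break       # singular basis: same for every combo
            feas = all((not np.isfinite(lo[j]) or sol[pos] >= Fraction(lo[j]))
                       and (not np.isfinite(hi[j]) or sol[pos] <= Fraction(hi[j]))
                       for pos, j in enumerate(basic))
            if not feas:
                continue
            obj = sum(c[j] * v for j, v in zip(nb, combo)) + \
                sum(c[j] * sol[pos] for pos, j in enumerate(basic))
            if best is None or obj < best[0]:
                x = [Fraction(0)] * nt
                for j, v in zip(nb, combo):
                    x[j] = v
                for pos, j in enumerate(basic):
                    x[j] = sol[pos]
                y = _frac_solve_T([[A[i][j] for j in basic] for i in range(m)],
                                  [c[j] for j in basic])
                st = np.full(nt, 1, dtype=np.int8)
                for pos, j in enumerate(basic):
                    st[j] = 0
                for j, v in zip(nb, combo):
                    at_up = (np.isfinite(hi[j]) and v == Fraction(hi[j])
                             and not (np.isfinite(lo[j]) and Fraction(lo[j]) == v))
                    st[j] = 2 if at_up else (1 if np.isfinite(lo[j]) else 3)
                best = (obj, x, y, st, list(basic))
    return best


def _frac_solve(M, rhs):
    n = len(rhs)
    M = [row[:] + [rhs[i]] for i, row in enumerate(M)]
    for k in range(n):
        piv = next((r for r in range(k, n) if M[r][k] != 0), None)
        if piv is None:
            return None
        M[k], M[piv] = M[piv], M[k]
        inv = Fraction(1) / M[k][k]
        M[k] = [v * inv for v in M[k]]
        for r in range(n):
            if r != k and M[r][k] != 0:
                f = M[r][k]
                M[r] = [a - f * bb for a, bb in zip(M[r], M[k])]
    return [M[i][n] for i in range(n)]


def _frac_solve_T(M, rhs):
    n = len(rhs)
    MT = [[M[j][i] for j in range(n)] for i in range(n)]
    return _frac_solve(MT, rhs)


@pytest.fixture
def tiny_lp():
    """min -v1 - v2  s.t.  v1 + v2 = 1,  0 <= v <= 1  (objective -1)."""
    S = SparseMatrix.from_dense([[1.0, 1.0]])
    return LPProblem(S, ["E"], np.array([1.0]), np.array([-1.0, -1.0]),
                     np.zeros(2), np.ones(2))
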