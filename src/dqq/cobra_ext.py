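"""ME/FBA formulation machinery.

Coupling constraints, coefficient lifting, stoichiometric-consistency
screening, flux variability analysis (FVA) and growth-rate bisection — the
standard constraint-based-modeling operations that surround the solver.

All operations are pure LP transformations on :class:`LPProblem`; solving
goes through the simplex engine (single-context) or the three-step driver,
whichever the caller requests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arith import QUAD
from .linalg import BASIC, BasisState
from .problem import (LPProblem, SparseMatrix, to_computational_form,
                      with_extra_rows)
from .simplex import (INFEASIBLE, OPTIMAL, SolverOptions, primal_simplex)


@dataclass
class CouplingSpec:
    """Ratio couplings c_min <= v_i / v_j <= c_max between nonnegative fluxes.

    ``k_eff`` optionally records, per (i, j) pair, the effective rate
    constant behind a growth-dependent ceiling c_max = mu / k_eff.
    """

    pairs: list[tuple[int, int, float, float]]      # (i, j, c_min, c_max)
    k_eff: dict[tuple[int, int], float] = field(default_factory=dict)
    mu: float | None = None

    def validate(self, p: LPProblem) -> None:
        for i, j, cmin, cmax in self.pairs:
            if cmin < 0 or cmax < cmin:
                raise ValueError(f"coupling ({i},{j}): need 0 <= c_min <= c_max")
            for jj in (i, j):
                if p.lower[jj] < 0:
                    raise ValueError(
                        f"coupling requires nonnegative fluxes, but column "
                        f"{p.col_names[jj]} has lower bound {p.lower[jj]}")
        for k in self.k_eff.values():
            if not (np.isfinite(k) and k > 0):
                raise ValueError("k_eff must be finite positive")


def add_coupling_constraints(p: LPProblem, spec: CouplingSpec) -> LPProblem:
    """Append the linear pair  v_i - c_max v_j <= 0,  -v_i + c_min v_j <= 0.

    The second row is omitted when c_min = 0 (vacuous for nonnegative
    fluxes).
    """
    spec.validate(p)
    rows = []
    for i, j, cmin, cmax in spec.pairs:
        ni, nj = p.col_names[i], p.col_names[j]
        rows.append(({i: 1.0, j: -cmax}, "L", 0.0, f"cpl_hi[{ni}/{nj}]"))
        if cmin > 0:
            rows.append(({i: -1.0, j: cmin}, "L", 0.0, f"cpl_lo[{ni}/{nj}]"))
    return with_extra_rows(p, rows)


def lift_large_coefficients(p: LPProblem, tau: float) -> LPProblem:
    """Split entries with |S_ij| > tau through auxiliary variables.

    Each offending entry K on column v_j is replaced by sign(K)*sqrt(|K|)
    applied to a new variable w defined by the auxiliary equality
    sqrt(|K|) * v_j - w = 0; the substitution leaves the optimal objective
    unchanged.  Passes repeat until every entry is at most tau, so very
    large coefficients are split recursively.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    q = p.copy()
    counter = 0
    while q.S.max_abs() > tau:
        offenders = [(i, j, v) for i, j, v in q.S.entries() if abs(v) > tau]
        # one aux per (column, magnitude) occurrence this pass
        new_cols = []
        new_rows = []
        S = SparseMatrix(q.m + len(offenders), q.n + len(offenders))
        for i, j, v in q.S.entries():
            if abs(v) <= tau:
                S.add(i, j, v)
        for t, (i, j, v) in enumerate(offenders):
            root = math.sqrt(abs(v))
            w_idx = q.n + t
            aux_row = q.m + t
            S.add(i, w_idx, math.copysign(root, v))
            S.add(aux_row, j, root, accumulate=True)
            S.add(aux_row, w_idx, -1.0)
            new_cols.append((f"lift_w{counter + t}",))
            new_rows.append((f"lift_r{counter + t}",))
        senses = list(q.row_sense) + ["E"] * len(offenders)
        rhs = np.concatenate([q.rhs, np.zeros(len(offenders))])
        ranges = (np.concatenate([q.ranges, np.full(len(offenders), np.nan)])
                  if q.ranges is not None else None)
        c = np.concatenate([q.c, np.zeros(len(offenders))])
        lo = np.concatenate([q.lower, np.full(len(offenders), -np.inf)])
        hi = np.concatenate([q.upper, np.full(len(offenders), np.inf)])
        row_names = list(q.row_names) + [r[0] for r in new_rows]
        col_names = list(q.col_names) + [cn[0] for cn in new_cols]
        q = LPProblem(S, senses, rhs, c, lo, hi, row_names, col_names,
                      q.sense, q.objective_constant, ranges, q.name + "-lift")
        counter += len(offenders)
    return q


def consistency_check(S: SparseMatrix, alpha: float = 1e-4, beta: float = 1e4,
                      opts: SolverOptions | None = None
                      ) -> tuple[np.ndarray, set[int]]:
    """Screen rows (molecular species) for stoichiometric inconsistency.

    A network is stoichiometrically consistent when strictly positive
    molecular masses ell exist with S^T ell = 0.  The cardinality objective
    (count the rows that can carry positive mass) is relaxed linearly:

        maximize sum(z)  s.t.  S^T ell = 0,  z <= ell,
                               0 <= z <= alpha, 0 <= ell <= beta,

    with alpha/beta proportional to the smallest mass considered nonzero and
    the largest allowed.  Rows whose optimal ell_i stays below alpha are
    flagged as inconsistency candidates.
    """
    if not (0 < alpha < beta):
        raise ValueError("need 0 < alpha < beta")
    m, n = S.n_rows, S.n_cols
    # variables: ell (m) then z (m)
    big = SparseMatrix(n + m, 2 * m)
    for i, j, v in S.entries():          # S^T ell = 0 rows (one per reaction)
        big.add(j, i, v)
    for i in range(m):                   # z_i - ell_i <= 0
        big.add(n + i, i, -1.0)
        big.add(n + i, m + i, 1.0)
    senses = ["E"] * n + ["L"] * (n + m - n)
    rhs = np.zeros(n + m)
    c = np.concatenate([np.zeros(m), np.ones(m)])
    lo = np.zeros(2 * m)
    hi = np.concatenate([np.full(m, beta), np.full(m, alpha)])
    lp = LPProblem(big, senses, rhs, c, lo, hi, sense="max",
                   name="consistency")
    if opts is None:
        opts = SolverOptions(ctx=QUAD, feasibility_tol=1e-15,
                             optimality_tol=1e-15, lu_factor_tol=10.0,
                             lu_update_tol=10.0)
    res = primal_simplex(to_computational_form(lp), opts)
    if res.status != OPTIMAL:
        return np.zeros(m), set(range(m))
    ell = np.array([float(res.v[i]) for i in range(m)])
    flagged = {i for i in range(m) if ell[i] < alpha * (1 - 1e-9)}
    return ell, flagged


@dataclass
class FVAResult:
    gamma: float
    Z0: float
    indices: list[int]
    minima: np.ndarray
    maxima: np.ndarray
    statuses: list[tuple[str, str]]

    def width(self, k: int) -> float:
        return self.maxima[k] - self.minima[k]


def flux_variability(p: LPProblem, gamma: float = 1.0,
                     indices: list[int] | None = None, warm: bool = True,
                     opts: SolverOptions | None = None,
                     Z0: float | None = None) -> FVAResult:
    """Per-flux min/max subject to near-optimality of the objective.

    First solves the flux-balance problem for Z0 (unless given), then for
    each requested column j solves min v_j and max v_j under the original
    constraints plus  c^T v >= gamma * Z0  (sense mirrored for minimization
    problems).  Consecutive solves warm-start from the previous basis: the
    appended objective row's slack starts basic, and min->max->next-column
    transitions typically need a handful of pivots.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma in (0, 1]")
    if opts is None:
        opts = SolverOptions(ctx=QUAD, feasibility_tol=1e-15,
                             optimality_tol=1e-15, lu_factor_tol=10.0,
                             lu_update_tol=10.0)
    if indices is None:
        indices = list(range(p.n))
    base_res = None
    if Z0 is None:
        base_res = primal_simplex(to_computational_form(p), opts)
        if base_res.status != OPTIMAL:
            raise ValueError(f"base problem not optimal: {base_res.status}")
        Z0 = base_res.objective
    has_obj = np.any(p.c != 0)
    if has_obj:
        sense = "G" if p.sense == "max" else "L"
        coeffs = {j: float(p.c[j]) for j in range(p.n) if p.c[j] != 0.0}
        limited = with_extra_rows(p, [(coeffs, sense, gamma * Z0, "fva_obj")])
    else:
        limited = p.copy()
    form = to_computational_form(limited)
    nt = form.n_total

    start = None
    if base_res is not None and has_obj:
        # extend the base-solve basis with the new objective row's slack
        st = np.concatenate([base_res.basis.statuses,
                             np.array([BASIC], dtype=np.int8)])
        start = BasisState(st.astype(np.int8),
                           list(base_res.basis.basic) + [nt - 1])

    minima = np.empty(len(indices))
    maxima = np.empty(len(indices))
    statuses = []
    for k, j in enumerate(indices):
        row = []
        for direction in ("min", "max"):
            c2 = np.zeros(nt)
            c2[j] = 1.0 if direction == "min" else -1.0
            f2 = form
            f2 = _with_objective(form, c2)
            res = primal_simplex(f2, opts, start if warm else None)
            if res.status == UNBOUNDED_STR:
                val = -np.inf if direction == "min" else np.inf
                row.append((val, res.status))
            elif res.status != OPTIMAL:
                raise ValueError(
                    f"FVA subproblem ({direction} col {j}) ended {res.status}"
                    " — inconsistent Z0?" if res.status == INFEASIBLE else
                    f"FVA subproblem ({direction} col {j}) ended {res.status}")
            else:
                row.append((float(res.v[j]), res.status))
                if warm:
                    start = res.basis
        minima[k] = row[0][0]
        maxima[k] = row[1][0]
        if minima[k] > maxima[k]:
            # tolerance-level inversion at a pinned flux: snap to midpoint
            if minima[k] - maxima[k] > 1e-6 * (1 + abs(minima[k])):
                raise RuntimeError(f"FVA min > max for column {j} beyond "
                                   "solver tolerance")
            minima[k] = maxima[k] = 0.5 * (minima[k] + maxima[k])
        statuses.append((row[0][1], row[1][1]))
    return FVAResult(gamma, Z0, list(indices), minima, maxima, statuses)


UNBOUNDED_STR = "unbounded"


def _with_objective(form, c_new):
    from dataclasses import replace as _replace
    return _replace(form, c=np.asarray(c_new, dtype=float), sense_sign=1,
                    objective_constant=0.0)


def max_growth_bisection(builder, mu_lo: float, mu_hi: float,
                         tol_mu: float = 1e-6,
                         opts: SolverOptions | None = None) -> dict:
    """Largest growth rate mu keeping builder(mu) feasible.

    ``builder`` maps a fixed mu to an :class:`LPProblem` (the growth-coupled
    constraints become linear once mu is fixed).  Feasibility must be
    monotone across [mu_lo, mu_hi] with exactly one feasible endpoint: the
    classical orientation is feasible at mu_lo (growth demands eventually
    exceed capacity) and the returned mu* is the largest feasible value;
    when instead mu_hi is the feasible endpoint (capacity constraints relax
    with growth), mu* is the smallest feasible value.  Either way
    builder(mu*) is feasible and the opposite side of the +-tol_mu interval
    is not.  Each test is a phase-1 solve (zero objective) warm-started from
    the previous test's basis when shapes allow; quad precision by default
    so near-threshold tests are decided reliably.
    """
    if opts is None:
        opts = SolverOptions(ctx=QUAD, feasibility_tol=1e-15,
                             optimality_tol=1e-15, lu_factor_tol=10.0,
                             lu_update_tol=10.0)
    solves = 0
    basis_memo = {"basis": None, "shape": None}

    def feasible(mu: float) -> bool:
        nonlocal solves
        p = builder(mu)
        form = to_computational_form(p)
        form = _with_objective(form, np.zeros(form.n_total))
        start = None
        if basis_memo["shape"] == (form.m, form.n_total):
            start = basis_memo["basis"]
        res = primal_simplex(form, opts, start)
        solves += 1
        if res.status == OPTIMAL:
            basis_memo["basis"] = res.basis
            basis_memo["shape"] = (form.m, form.n_total)
            return True
        if res.status == INFEASIBLE:
            return False
        raise RuntimeError(f"feasibility test at mu={mu} ended {res.status}")

    feas_lo = feasible(mu_lo)
    feas_hi = feasible(mu_hi)
    if feas_lo and feas_hi:
        raise ValueError(f"builder is feasible at both mu_lo={mu_lo} and "
                         f"mu_hi={mu_hi}; widen the interval")
    if not feas_lo and not feas_hi:
        raise ValueError(f"builder is infeasible at both mu_lo={mu_lo} and "
                         f"mu_hi={mu_hi}; widen the interval")
    lo, hi = mu_lo, mu_hi
    while hi - lo > tol_mu:
        mid = 0.5 * (lo + hi)
        if feasible(mid) == feas_lo:
            lo = mid
        else:
            hi = mid
    mu_star = lo if feas_lo else hi
    return {"mu_star": mu_star, "interval": (lo, hi), "solves": solves,
            "feasible_side": "low" if feas_lo else "high"}
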