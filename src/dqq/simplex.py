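"""Revised primal simplex (phases 1 and 2) over any arithmetic context.

The engine iterates the classical revised cycle — factorize/update B, solve
B^T y = c_B, price z_N = c_N - N^T y, choose the entering variable (Dantzig:
most violating reduced cost), solve B d = a_q, run the EXPAND ratio test,
pivot — with:

* phase 1 minimizing the sum of bound infeasibilities through the same
  machinery (costs are the infeasibility gradient of the basic variables);
* EXPAND anti-degeneracy: the working feasibility tolerance grows by
  (delta1 - delta1/2)/expand_frequency per iteration, ties are broken by the
  largest pivot element, every step is at least increment/|pivot| long, and
  the tolerance resets (with a fresh factorization and recomputed basics)
  every expand_frequency iterations;
* bound flips for boxed nonbasic variables;
* warm starts from any consistent basis, with basis repair when the starting
  basis factorizes as singular.

A ``classic_ratio_test`` option disables the EXPAND floor (textbook minimum
ratio, lowest-index tie-break).  It exists to demonstrate cycling/stalling on
degenerate problems and is never used by the production drivers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .arith import ArithmeticContext, DOUBLE, extended, inf_norm
from .linalg import (AT_LOWER, AT_UPPER, BASIC, FREE, BasisState,
                     SingularBasisError, factorize, repair_basis, slack_basis,
                     update_after_pivot)
from .problem import ComputationalForm

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
ITERATION_LIMIT = "iteration_limit"
NUMERIC_ERROR = "numeric_error"


@dataclass
class SolverOptions:
    """Runtime options (the per-step tables of the three-step driver)."""

    scale: bool = True
    feasibility_tol: float = 1e-6          # delta_1
    optimality_tol: float = 1e-6           # delta_2
    expand_frequency: int = 10000
    lu_factor_tol: float = 100.0
    lu_update_tol: float = 10.0
    iteration_limit: int | None = None
    refactor_frequency: int = 100
    ctx: ArithmeticContext = DOUBLE
    pricing: str = "dantzig"               # "partial" reserved, not implemented
    classic_ratio_test: bool = False       # disables the EXPAND step floor
    dj_tol_absolute: bool = False          # price against delta2 itself, not
    #                                        delta2*(1+||y||): the zoomed
    #                                        problems of iterative refinement
    #                                        are built so violations are O(1)
    refine_solves: int = 0                 # refinement passes on basis solves
    verbosity: int = 0

    def __post_init__(self):
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.expand_frequency < 1:
            raise ValueError("expand_frequency must be >= 1")
        if self.lu_factor_tol < 1 or self.lu_update_tol < 1:
            raise ValueError("LU tolerances must be >= 1")


@dataclass
class SimplexResult:
    status: str
    v: np.ndarray                  # structural + slack values (length n + m)
    y: np.ndarray                  # duals per row
    z: np.ndarray                  # reduced costs, length n + m
    objective: float               # original-sense objective
    iterations: int
    degenerate_iterations: int
    Pinf: float
    Dinf: float
    basis: BasisState
    phase1_iterations: int = 0
    basis_repairs: int = 0
    refactorizations: int = 0
    log: list = field(default_factory=list)
    wall_time: float = 0.0
    ray: np.ndarray | None = None  # certificate when unbounded


def compute_infeasibilities(form: ComputationalForm, x, y,
                            statuses=None, dps: int = 50):
    """Maximum primal and dual infeasibility of a candidate point.

    Measured on the data of ``form`` (callers pass the *original unscaled*
    form for certification) in an mpmath context of at least quad precision.
    Pinf is the worst violation of A x = b and of the variable bounds; Dinf
    is the worst reduced-cost sign violation given each variable's status
    (at lower: z_j >= 0; at upper: z_j <= 0; basic or free: z_j = 0).
    """
    hi = extended(max(dps, 34))
    with hi.workprec():
        xh = hi.array(x)
        n, m = form.n_struct, form.m
        res = form.S.matvec(xh[:n]) - xh[n:] - hi.array(form.b)
        pinf = inf_norm(res)
        for j in range(n + m):
            lo, up = form.lower[j], form.upper[j]
            if np.isfinite(lo) and xh[j] < lo:
                pinf = max(pinf, lo - xh[j])
            if np.isfinite(up) and xh[j] > up:
                pinf = max(pinf, xh[j] - up)
        yh = hi.array(y)
        zs = hi.array(form.c[:n]) - form.S.rmatvec(yh)
        zslack = hi.array(form.c[n:]) + yh        # slack columns are -e_i
        z = np.concatenate([zs, zslack])
        dinf = hi.scalar(0)
        if statuses is None:
            statuses = np.full(n + m, FREE, dtype=np.int8)
        for j in range(n + m):
            st = statuses[j]
            zj = z[j]
            if st == AT_LOWER:
                viol = -zj if zj < 0 else hi.scalar(0)
            elif st == AT_UPPER:
                viol = zj if zj > 0 else hi.scalar(0)
            else:                  # basic or free: z_j should vanish
                viol = abs(zj)
            if viol > dinf:
                dinf = viol
        return pinf, dinf


def expand_ratio_test(delta, x_B, lo_B, hi_B, entering_span, tol_work,
                      increment, pivot_tol, scale_lo=None, scale_hi=None,
                      classic: bool = False):
    """Choose the blocking variable (or bound flip) and the step length.

    ``delta`` is the per-unit change of each basic variable, ``entering_span``
    the width of the entering variable's own range.  ``scale_lo``/``scale_hi``
    give the per-variable tolerance scale 1 + |bound| (ones when omitted), so
    all tolerances are relative to each bound's own magnitude.  Returns
    (kind, position, step, bound) with kind in {"pivot", "flip", "unbounded"}
    and bound in {"lower", "upper"}.

    EXPAND: pass 1 finds the largest step permitted when every blocking bound
    is relaxed by the post-iteration working tolerance; pass 2 picks, among
    candidates blocking within that step, the one with the largest |pivot|,
    and the returned step is never smaller than increment/|pivot|.
    """
    m = len(x_B)
    if scale_lo is None:
        scale_lo = np.ones(m)
    if scale_hi is None:
        scale_hi = np.ones(m)
    cands = []                 # (plain ratio, |pivot|, position, bound, scale)
    theta_exp = None
    for i in range(m):
        d = delta[i]
        ad = abs(d)
        if ad <= pivot_tol:
            continue
        xi, lo, hi = x_B[i], lo_B[i], hi_B[i]
        tlo = tol_work * scale_lo[i]
        thi = tol_work * scale_hi[i]
        if d < 0:                  # moving down
            if xi > hi + thi and np.isfinite(hi):
                target, bound, sc = hi, "upper", scale_hi[i]
            elif xi >= lo - tlo and np.isfinite(lo):
                target, bound, sc = lo, "lower", scale_lo[i]
            else:
                continue
        else:                      # moving up
            if xi < lo - tlo and np.isfinite(lo):
                target, bound, sc = lo, "lower", scale_lo[i]
            elif xi <= hi + thi and np.isfinite(hi):
                target, bound, sc = hi, "upper", scale_hi[i]
            else:
                continue
        dist = (target - xi) / d   # >= -tol/|d|
        if dist < 0:
            dist = 0 * dist
        cands.append((dist, ad, i, bound, sc))
        t_exp = dist + (tol_work + increment) * sc / ad
        if theta_exp is None or t_exp < theta_exp:
            theta_exp = t_exp

    if theta_exp is None:
        if np.isfinite(entering_span):
            return "flip", -1, entering_span, ""
        return "unbounded", -1, None, ""

    if classic:
        best = min(cands, key=lambda c: (c[0], c[2]))
        dist, ad, i, bound, _ = best
        if entering_span <= dist:
            return "flip", -1, entering_span, ""
        return "pivot", i, dist, bound

    if entering_span <= theta_exp:
        # the entering variable reaches its opposite bound first
        blockers = [c for c in cands if c[0] <= entering_span]
        if not blockers:
            return "flip", -1, entering_span, ""
    blockers = [c for c in cands if c[0] <= theta_exp]
    dist, ad, i, bound, sc = max(blockers, key=lambda c: (c[1], -c[2]))
    step = dist
    floor = increment * sc / ad
    if step < floor:
        step = floor
    if entering_span < step:
        return "flip", -1, entering_span, ""
    return "pivot", i, step, bound


def primal_simplex(form: ComputationalForm, opts: SolverOptions,
                   start: BasisState | None = None) -> SimplexResult:
    """Solve a computational-form LP; see module docstring for the cycle."""
    t0 = time.time()
    ctx = opts.ctx
    with ctx.workprec():
        return _primal_simplex_inner(form, opts, start, t0)


def _primal_simplex_inner(form, opts, start, t0):
    ctx = opts.ctx
    m, n = form.m, form.n_struct
    nt = n + m
    A = form.dense_A(ctx)
    b = ctx.array(form.b)
    c = ctx.array(form.c)
    lo = np.asarray(form.lower)
    hi = np.asarray(form.upper)
    delta1 = opts.feasibility_tol
    delta2 = opts.optimality_tol
    K = opts.expand_frequency
    increment = 0.5 * delta1 / K
    pivot_tol = float(ctx.eps) ** (2.0 / 3.0)
    itn_limit = (opts.iteration_limit if opts.iteration_limit is not None
                 else 200 * (m + n) + 2000)
    log: list[str] = []

    basis = start.copy() if start is not None else slack_basis(form)
    basis.validate(m, nt)

    # per-variable feasibility-tolerance scales: 1 + |bound|
    scale_lo_all = np.where(np.isfinite(lo), 1.0 + np.abs(lo), 1.0)
    scale_hi_all = np.where(np.isfinite(hi), 1.0 + np.abs(hi), 1.0)

    x = ctx.zeros(nt)
    for j in range(nt):
        st = basis.statuses[j]
        if st == AT_LOWER:
            x[j] = ctx.scalar(lo[j]) if np.isfinite(lo[j]) else ctx.scalar(0)
        elif st == AT_UPPER:
            x[j] = ctx.scalar(hi[j]) if np.isfinite(hi[j]) else ctx.scalar(0)
        else:
            x[j] = ctx.scalar(0)

    repairs = 0
    refactorizations = 0

    def refactor(current_basis):
        nonlocal repairs, refactorizations
        for attempt in range(4):
            B = A[:, current_basis.basic]
            f = factorize(B, opts.lu_factor_tol, ctx,
                          max_updates=opts.refactor_frequency)
            refactorizations += 1
            if not f.dependents:
                return f, current_basis
            current_basis, rlog = repair_basis(current_basis, f.dependents,
                                               form, values=x)
            repairs += len(f.dependents)
            log.extend(rlog)
        raise SingularBasisError("basis unrepairable")

    entries = list(form.S.entries())      # sparse structural data, floats

    def recompute_basics(f, current_basis):
        if ctx.is_double:
            xs = x.copy()
            for k in current_basis.basic:
                xs[k] = 0.0
            rhs = b - A @ xs
        else:
            rhs = b.copy()
            in_basis = np.zeros(nt, dtype=bool)
            in_basis[current_basis.basic] = True
            for i, j, v in entries:
                if not in_basis[j] and x[j] != 0:
                    rhs[i] = rhs[i] - v * x[j]
            for i in range(m):
                j = n + i
                if not in_basis[j] and x[j] != 0:
                    rhs[i] = rhs[i] + x[j]
        xb = f.solve(rhs, refine=opts.refine_solves)
        for pos, k in enumerate(current_basis.basic):
            x[k] = xb[pos]

    try:
        factors, basis = refactor(basis)
    except SingularBasisError:
        return _finalize(form, ctx, x, ctx.zeros(m), basis, NUMERIC_ERROR,
                         0, 0, 0, repairs, refactorizations, log, t0)
    recompute_basics(factors, basis)

    tol_work = 0.5 * delta1
    iters = 0
    degen = 0
    phase1_iters = 0
    cleanup_rounds = 0
    status = None
    ray = None

    while True:
        if iters >= itn_limit:
            status = ITERATION_LIMIT
            break

        # -- classify feasibility of the basics --------------------------
        lo_B = lo[basis.basic]
        hi_B = hi[basis.basic]
        x_B = x[basis.basic]
        sc_lo_B = scale_lo_all[basis.basic]
        sc_hi_B = scale_hi_all[basis.basic]
        # phase classification at the full delta1, scaled per bound (the
        # working EXPAND tolerance, which breathes between delta1/2 and
        # delta1, applies only to the ratio test) — otherwise borderline
        # violations flip the solver between phases forever
        viol_lo = []
        viol_hi = []
        for pos in range(m):
            if (np.isfinite(lo_B[pos])
                    and x_B[pos] < lo_B[pos] - delta1 * sc_lo_B[pos]):
                viol_lo.append(pos)
            elif (np.isfinite(hi_B[pos])
                    and x_B[pos] > hi_B[pos] + delta1 * sc_hi_B[pos]):
                viol_hi.append(pos)
        phase = 1 if (viol_lo or viol_hi) else 2
        if opts.verbosity >= 2 and iters % 200 == 0:
            sum_inf = sum(float(lo_B[p2] - x_B[p2]) for p2 in viol_lo) + \
                sum(float(x_B[p2] - hi_B[p2]) for p2 in viol_hi)
            print(f"itn {iters} phase {phase} ninf {len(viol_lo)+len(viol_hi)} "
                  f"suminf {sum_inf:.3e} "
                  f"obj {float(form.objective_value(x)):.6e}")

        # -- duals and pricing -------------------------------------------
        if phase == 1:
            cost_B = ctx.zeros(m)
            for pos in viol_lo:
                cost_B[pos] = ctx.scalar(-1)
            for pos in viol_hi:
                cost_B[pos] = ctx.scalar(1)
            cvec = None
        else:
            cost_B = c[basis.basic]
            cvec = c
        y = factors.solve_T(cost_B, refine=opts.refine_solves)
        if ctx.is_double:
            zfull = (c if phase == 2 else ctx.zeros(nt)) - y @ A
        else:
            # sparse pricing: z = c - [S -I]^T y
            zfull = c.copy() if phase == 2 else ctx.zeros(nt)
            for i, j, v in entries:
                if y[i] != 0:
                    zfull[j] = zfull[j] - v * y[i]
            zfull[n:] = zfull[n:] + y
        dj_tol = delta2 if opts.dj_tol_absolute else \
            delta2 * (1 + float(inf_norm(y)))

        entering = -1
        best_viol = dj_tol
        for j in range(nt):
            st = basis.statuses[j]
            if st == BASIC:
                continue
            zj = zfull[j]
            if st == AT_LOWER:
                viol = -zj
            elif st == AT_UPPER:
                viol = zj
            else:                  # FREE
                viol = abs(zj)
            if viol > best_viol:
                best_viol = viol
                entering = j
        if entering < 0:
            # optimality (phase 2) or phase-1 stationarity
            if phase == 1:
                if cleanup_rounds < 3:
                    cleanup_rounds += 1
                    factors, basis = refactor(basis)
                    recompute_basics(factors, basis)
                    tol_work = 0.5 * delta1
                    continue
                status = INFEASIBLE
                break
            if cleanup_rounds < 3 and factors.update_count > 0:
                cleanup_rounds += 1
                factors, basis = refactor(basis)
                recompute_basics(factors, basis)
                tol_work = 0.5 * delta1
                continue
            status = OPTIMAL
            break

        # -- direction ----------------------------------------------------
        a_q = A[:, entering]
        w = factors.solve(a_q, refine=opts.refine_solves)
        st_q = basis.statuses[entering]
        if st_q == AT_LOWER:
            s = 1
        elif st_q == AT_UPPER:
            s = -1
        else:
            s = 1 if zfull[entering] < 0 else -1
        delta_B = -s * w                      # change of basics per unit step
        span = hi[entering] - lo[entering] if (np.isfinite(lo[entering])
                                               and np.isfinite(hi[entering])) \
            else np.inf

        kind, pos, step, bound = expand_ratio_test(
            delta_B, x_B, lo_B, hi_B, span, tol_work, increment, pivot_tol,
            scale_lo=sc_lo_B, scale_hi=sc_hi_B,
            classic=opts.classic_ratio_test)

        if kind == "unbounded":
            if phase == 2:
                ray = ctx.zeros(nt)
                ray[entering] = ctx.scalar(s)
                for p2, kvar in enumerate(basis.basic):
                    ray[kvar] = delta_B[p2]
                status = UNBOUNDED
            else:
                status = NUMERIC_ERROR
                log.append("phase-1 direction unbounded: numeric failure")
            break

        step = ctx.scalar(step)
        if kind == "pivot":
            piv = max(float(abs(delta_B[pos])), 1e-300)
            sc_deg = float(max(sc_lo_B[pos], sc_hi_B[pos]))
            if float(step) <= 1.01 * increment * sc_deg / piv:
                degen += 1
        if phase == 1:
            phase1_iters += 1

        # -- apply the step ----------------------------------------------
        x[entering] = x[entering] + s * step
        xb_new = x_B + delta_B * step
        for p2, kvar in enumerate(basis.basic):
            x[kvar] = xb_new[p2]

        if kind == "flip":
            basis.statuses[entering] = AT_UPPER if s > 0 else AT_LOWER
            x[entering] = ctx.scalar(hi[entering] if s > 0 else lo[entering])
        else:
            leaving = basis.basic[pos]
            basis.statuses[leaving] = AT_LOWER if bound == "lower" else AT_UPPER
            x[leaving] = ctx.scalar(lo[leaving] if bound == "lower"
                                    else hi[leaving])
            basis.statuses[entering] = BASIC
            basis.basic[pos] = entering
            ok = update_after_pivot(factors, w, pos, opts.lu_update_tol, ctx)
            if not ok:
                try:
                    factors, basis = refactor(basis)
                except SingularBasisError:
                    status = NUMERIC_ERROR
                    break
                recompute_basics(factors, basis)

        iters += 1
        tol_work += increment
        if iters % K == 0 or tol_work >= delta1:
            tol_work = 0.5 * delta1
            factors, basis = refactor(basis)
            recompute_basics(factors, basis)

    # -- finalize ---------------------------------------------------------
    cost_B = c[basis.basic]
    try:
        y = factors.solve_T(cost_B, refine=opts.refine_solves)
    except Exception:
        y = ctx.zeros(m)
    return _finalize(form, ctx, x, y, basis, status, iters, degen,
                     phase1_iters, repairs, refactorizations, log, t0, ray)


def _finalize(form, ctx, x, y, basis, status, iters, degen, phase1_iters,
              repairs, refactorizations, log, t0, ray=None):
    n, m = form.n_struct, form.m
    zs = ctx.array(form.c[:n]) - form.S.rmatvec(y)
    zslack = ctx.array(form.c[n:]) + y
    z = np.concatenate([zs, zslack])
    obj = float(form.objective_value(x))
    pinf, dinf = compute_infeasibilities(form, x, y, basis.statuses,
                                         dps=max(50, 2 * ctx.decimal_digits))
    return SimplexResult(status=status, v=x, y=y, z=z, objective=obj,
                         iterations=iters, degenerate_iterations=degen,
                         Pinf=pinf, Dinf=dinf, basis=basis,
                         phase1_iterations=phase1_iters,
                         basis_repairs=repairs,
                         refactorizations=refactorizations, log=log,
                         wall_time=time.time() - t0, ray=ray)
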