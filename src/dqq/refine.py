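"""The zoom strategy: iterative refinement of LP solutions.

Given an approximate primal/dual pair (x1, y1) for

    min c^T x   s.t.  A x = b,  l <= x <= u,

the residuals r1 = b - A x1 and d1 = c - A^T y1 are computed in elevated
precision, a magnification sigma = 1 / max(||r1||_inf, worst reduced-cost
sign violation, tiny) is chosen (capped per round), and the "zoomed" problem

    min (sigma d1)^T xhat   s.t.  A xhat = sigma r1,
                                  sigma (l - x1) <= xhat <= sigma (u - x1)

is solved with the same fixed-precision solver, warm-started from the
incumbent basis.  Its solution (xhat, yhat) is O(1) by construction, so an
absolute-tolerance solver handles it well, and the corrections

    x = x1 + xhat / sigma,     y = y1 + yhat / sigma

recover extra digits.  Repeating zooms with residuals computed at digit
counts that double per round drives max(Pinf, Dinf) toward the precision of
the residual context, even when every inner solve runs in plain double.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arith import DOUBLE, ArithmeticContext, extended, inf_norm, to_float_array
from .linalg import BasisState
from .problem import ComputationalForm
from .scaling import apply_scaling, compute_scales, unscale_solution
from .simplex import (OPTIMAL, SolverOptions,
                      compute_infeasibilities, primal_simplex)

#: Floor preventing sigma overflow when the incumbent is already (near) exact.
TINY_RESIDUAL = 1e-200


def compute_residuals(form: ComputationalForm, x, y,
                      ctx_high: ArithmeticContext):
    """(r, d) = (b - A x, c - A^T y) evaluated in ``ctx_high``."""
    with ctx_high.workprec():
        xh = ctx_high.array(x)
        yh = ctx_high.array(y)
        n, m = form.n_struct, form.m
        r = ctx_high.array(form.b) - (form.S.matvec(xh[:n]) - xh[n:])
        d_struct = ctx_high.array(form.c[:n]) - form.S.rmatvec(yh)
        d_slack = ctx_high.array(form.c[n:]) + yh
        return r, np.concatenate([d_struct, d_slack])


@dataclass
class ZoomState:
    rounds: list[dict] = field(default_factory=list)
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    basis: BasisState | None = None
    converged: bool = False
    stagnated: bool = False

    @property
    def trace(self) -> list[float]:
        return [rd["max_pd"] for rd in self.rounds]


#: Largest magnification applied in one round.  One round can therefore gain
#: at most ~9 digits; repeated rounds (with residuals at ever higher
#: precision) gain the rest.  Without the cap a tiny primal residual next to
#: a large dual error produces a zoomed problem whose data overwhelms the
#: fixed-precision inner solver.
SIGMA_CAP = 1.0e9


def _dual_sign_violation(d, statuses) -> float:
    worst = 0.0
    for j, dj in enumerate(d):
        st = statuses[j] if statuses is not None else FREE_STATUS
        v = float(dj)
        if st == 1:                  # at lower: d_j >= 0 wanted
            viol = max(0.0, -v)
        elif st == 2:                # at upper: d_j <= 0 wanted
            viol = max(0.0, v)
        else:                        # basic or free
            viol = abs(v)
        worst = max(worst, viol)
    return worst


FREE_STATUS = 3


def zoom_round(form: ComputationalForm, x1, y1, solver_opts: SolverOptions,
               basis: BasisState | None = None,
               residual_digits: int = 50):
    """One zoom: returns (x, y, (sigma_p, sigma_d), inner result).

    One magnification drives both spaces: sigma = 1 / max(||r1||_inf, worst
    reduced-cost sign violation given the incumbent's statuses, tiny),
    capped at SIGMA_CAP.  ``basis`` warm-starts the inner solve.
    """
    hi = extended(residual_digits)
    r, d = compute_residuals(form, x1, y1, hi)
    with hi.workprec():
        statuses = basis.statuses if basis is not None else None
        dual_err = _dual_sign_violation(d, statuses)
        # one magnification driven by the worse of the two errors: when the
        # dual error dominates (a near-feasible point with a suboptimal
        # basis) the primal correction is vertex-sized, and magnifying by
        # 1/||r|| alone would blow the zoomed problem out of the inner
        # solver's range
        sigma = min(1.0 / max(float(inf_norm(r)), dual_err, TINY_RESIDUAL),
                    SIGMA_CAP)
        sigma_p = sigma_d = sigma
        xh = hi.array(x1)
        lo = np.asarray(form.lower, dtype=float)
        up = np.asarray(form.upper, dtype=float)
        n_t = form.n_total
        lo2 = np.empty(n_t)
        up2 = np.empty(n_t)
        for j in range(n_t):
            lo2[j] = -np.inf if np.isneginf(lo[j]) else float(
                (hi.scalar(lo[j]) - xh[j]) * sigma_p)
            up2[j] = np.inf if np.isposinf(up[j]) else float(
                (hi.scalar(up[j]) - xh[j]) * sigma_p)
        b2 = np.array([float(v * sigma_p) for v in r])
        c2 = np.array([float(v * sigma_d) for v in d])
    zoomed = ComputationalForm(form.S, b2, c2, lo2, up2, sense_sign=1,
                               objective_constant=0.0,
                               row_names=list(form.row_names),
                               col_names=list(form.col_names))
    inner_opts = replace(solver_opts, dj_tol_absolute=True)
    # honor the Scale option for the inner solve: the zoomed data inherit
    # the original matrix's spread and double phase 1 may fail on them raw
    sc = None
    solve_form = zoomed
    if solver_opts.scale and zoomed.S.nnz and inner_opts.ctx.is_double:
        sc = compute_scales(zoomed.S, ctx=inner_opts.ctx)
        solve_form = apply_scaling(zoomed, sc)
    res = primal_simplex(solve_form, inner_opts, basis)
    if res.status != OPTIMAL:
        # inconsistent incumbent: fall back to a fresh solve of the zoomed
        # problem from the slack basis
        res = primal_simplex(solve_form, inner_opts, None)
    if sc is not None:
        xz, yz = unscale_solution(to_float_array(res.v),
                                  to_float_array(res.y), sc)
    else:
        xz, yz = res.v, res.y
    with hi.workprec():
        xcorr = hi.array(x1) + hi.array(xz) / hi.scalar(sigma_p)
        ycorr = hi.array(y1) + hi.array(yz) / hi.scalar(sigma_d)
    return xcorr, ycorr, (sigma_p, sigma_d), res


def zoom_refine(form: ComputationalForm, x0, y0,
                solver_opts: SolverOptions | None = None,
                basis: BasisState | None = None,
                rounds_max: int = 6, target_tol: float = 1e-30,
                base_digits: int = 32) -> ZoomState:
    """Repeat zoom rounds until max(Pinf, Dinf) meets the target.

    Residual precision starts at ``base_digits`` digits and doubles each
    round.  The per-round trace of max(Pinf, Dinf), measured at the highest
    residual precision used so far (>= 50 digits), must decrease strictly;
    a non-decreasing round stops the process with the best point kept.
    """
    if solver_opts is None:
        solver_opts = SolverOptions(feasibility_tol=1e-9, optimality_tol=1e-9,
                                    expand_frequency=100000,
                                    lu_factor_tol=5.0, lu_update_tol=5.0,
                                    ctx=DOUBLE)
    state = ZoomState()
    x, y = np.asarray(x0), np.asarray(y0)
    cur_basis = basis
    meas_digits = max(50, 2 * base_digits)

    def measure(xv, yv):
        st = cur_basis.statuses if cur_basis is not None else None
        pinf, dinf = compute_infeasibilities(form, xv, yv, st,
                                             dps=meas_digits)
        return float(pinf), float(dinf)

    pinf, dinf = measure(x, y)
    best = (max(pinf, dinf), x, y, cur_basis)
    xnorm = 1 + float(inf_norm(to_float_array(x)))
    ynorm = 1 + float(inf_norm(to_float_array(y)))
    if max(pinf, dinf) <= target_tol * max(xnorm, ynorm):
        state.x, state.y, state.basis = x, y, cur_basis
        state.converged = True
        return state

    digits = base_digits
    prev_pd = best[0]
    for rnd in range(1, rounds_max + 1):
        meas_digits = max(meas_digits, 2 * digits)
        x2, y2, (sigma_p, sigma_d), res = zoom_round(
            form, x, y, solver_opts, cur_basis, residual_digits=digits)
        cur_basis = res.basis
        pinf, dinf = measure(x2, y2)
        max_pd = max(pinf, dinf)
        state.rounds.append({"round": rnd, "sigma": sigma_p,
                             "sigma_dual": sigma_d, "Pinf": pinf,
                             "Dinf": dinf, "max_pd": max_pd,
                             "residual_digits": digits,
                             "inner_iterations": res.iterations})
        if max_pd < best[0]:
            best = (max_pd, x2, y2, cur_basis)
        if max_pd >= prev_pd:
            state.stagnated = True
            break
        prev_pd = max_pd
        x, y = x2, y2
        xnorm = 1 + float(inf_norm(to_float_array(x)))
        ynorm = 1 + float(inf_norm(to_float_array(y)))
        if max_pd <= target_tol * max(xnorm, ynorm):
            state.converged = True
            break
        digits *= 2
    _, state.x, state.y, state.basis = best
    return state
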