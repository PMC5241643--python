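"""Basis factorization: precision-generic LU, solves, updates, repair.

The basis matrix B (m x m, columns of [S -I]) is factorized by Gaussian
elimination with threshold partial pivoting: at each stage the pivot is
chosen among rows whose entry is within a factor ``lu_factor_tol`` of the
column maximum, preferring the sparsest admissible row (the stability /
sparsity trade the factor tolerance controls).  Columns whose best available
pivot falls below ``singularity_tol`` times the column norm are reported as
*dependent* rather than raising; the caller repairs the basis by making
slack variables basic and refactorizes.

After a simplex pivot the factors are updated in product form: the solved
entering column w = B^-1 a_q is kept as an eta vector.  When the update
pivot w_p is too small relative to ||w||_inf (growth beyond what the update
tolerance permits) or the eta file reaches ``refactor_frequency``, the update
is refused and the caller refactorizes — mirroring the singularity-after-
update behaviour large multiscale bases exhibit in double precision.

Optional iterative refinement (residual in a context with twice the working
digits, correction through the existing factors) is available on every solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arith import ArithmeticContext, extended, inf_norm

BASIC, AT_LOWER, AT_UPPER, FREE = 0, 1, 2, 3
_STATUS_NAMES = {BASIC: "basic", AT_LOWER: "nonbasic_at_lower",
                 AT_UPPER: "nonbasic_at_upper", FREE: "nonbasic_free"}


@dataclass
class BasisState:
    """Simplex basis: per-variable status plus the ordered basic list."""

    statuses: np.ndarray            # int8 per variable
    basic: list[int]                # length m, position -> variable index

    def copy(self) -> "BasisState":
        return BasisState(self.statuses.copy(), list(self.basic))

    def validate(self, m: int, n_total: int, lower=None, upper=None) -> None:
        if len(self.basic) != m:
            raise ValueError(f"basis needs exactly {m} basic variables")
        if self.statuses.shape != (n_total,):
            raise ValueError("status vector has wrong length")
        counts = np.bincount(self.statuses, minlength=4)
        if counts[BASIC] != m or sorted(set(self.basic)) != sorted(self.basic):
            raise ValueError("statuses inconsistent with basic list")
        for k in self.basic:
            if self.statuses[k] != BASIC:
                raise ValueError(f"variable {k} in basic list but not basic")


def slack_basis(form) -> BasisState:
    """Cold-start all-logical basis.

    Slacks are basic; nonbasic structurals start at the bound nearer their
    cost direction (minimization), falling back to whichever bound is finite.
    """
    n, m = form.n_struct, form.m
    statuses = np.empty(n + m, dtype=np.int8)
    for j in range(n):
        lo, hi = form.lower[j], form.upper[j]
        if np.isinf(lo) and np.isinf(hi):
            statuses[j] = FREE
        elif np.isinf(lo):
            statuses[j] = AT_UPPER
        elif np.isinf(hi):
            statuses[j] = AT_LOWER
        else:
            statuses[j] = AT_UPPER if form.c[j] < 0 else AT_LOWER
    statuses[n:] = BASIC
    return BasisState(statuses, list(range(n, n + m)))


class SingularBasisError(RuntimeError):
    pass


@dataclass
class LUFactors:
    """Compact LU of (a possibly repaired copy of) B with eta updates."""

    m: int
    ctx: ArithmeticContext
    LU: np.ndarray                  # L strictly below diagonal, U on/above
    perm: list[int]                 # pivot row order: (LU)[k] is row perm[k] of B
    B: np.ndarray                   # the matrix as factorized (dense, ctx dtype)
    lu_factor_tol: float
    dependents: list[tuple[int, int]] = field(default_factory=list)
    etas: list[tuple[int, np.ndarray]] = field(default_factory=list)
    max_updates: int = 100

    @property
    def update_count(self) -> int:
        return len(self.etas)

    # -- triangular kernels ----------------------------------------------
    def _solve_lu(self, rhs: np.ndarray) -> np.ndarray:
        m, LU = self.m, self.LU
        y = rhs[self.perm].copy()
        for k in range(m):
            if k and LU[k, :k].any():
                y[k] = y[k] - LU[k, :k] @ y[:k]
        for k in range(m - 1, -1, -1):
            if k < m - 1 and LU[k, k + 1:].any():
                y[k] = y[k] - LU[k, k + 1:] @ y[k + 1:]
            y[k] = y[k] / LU[k, k]
        return y

    def _solve_lu_T(self, rhs: np.ndarray) -> np.ndarray:
        m, LU = self.m, self.LU
        z = rhs.copy()
        for k in range(m):
            z[k] = z[k] / LU[k, k]
            if k < m - 1 and LU[k, k + 1:].any():
                z[k + 1:] = z[k + 1:] - LU[k, k + 1:] * z[k]
        for k in range(m - 1, -1, -1):
            if k and LU[k, :k].any():
                z[:k] = z[:k] - LU[k, :k] * z[k]
        out = np.empty_like(z)
        out[self.perm] = z
        return out

    # -- public solves ----------------------------------------------------
    def solve(self, rhs, refine: int = 0) -> np.ndarray:
        """x with B x = rhs (B including any eta updates)."""
        x = self._solve_lu(np.asarray(rhs))
        for pos, w in self.etas:
            xp = x[pos] / w[pos]
            x = x - w * xp
            x[pos] = xp
        if refine:
            x = self._refine(x, np.asarray(rhs), transpose=False, passes=refine)
        return x

    def solve_T(self, rhs, refine: int = 0) -> np.ndarray:
        """y with B^T y = rhs."""
        g = np.asarray(rhs).copy()
        for pos, w in reversed(self.etas):
            gp = g[pos]
            g[pos] = 0 * gp
            g[pos] = (gp - w @ g) / w[pos]
        y = self._solve_lu_T(g)
        if refine:
            y = self._refine(y, np.asarray(rhs), transpose=True, passes=refine)
        return y

    def _refine(self, x, rhs, transpose: bool, passes: int) -> np.ndarray:
        hi = extended(max(32, 2 * self.ctx.decimal_digits))
        for _ in range(passes):
            with hi.workprec():
                xh = hi.array(x)
                Bh = self.B if not self.ctx.is_double else hi.array(self.B)
                if not transpose:
                    prod = self._apply_exact(Bh, xh, False)
                else:
                    prod = self._apply_exact(Bh, xh, True)
                r = hi.array(rhs) - prod
            rl = r if not self.ctx.is_double else np.array(
                [float(v) for v in r])
            corr = (self.solve(rl, refine=0) if not transpose
                    else self.solve_T(rl, refine=0))
            x = x + corr
        return x

    def _apply_exact(self, Bh, x, transpose: bool) -> np.ndarray:
        """(updated B) @ x or its transpose, in the caller's precision."""
        if not transpose:
            v = x.copy()
            for pos, w in reversed(self.etas):
                vp = v[pos]
                delta = w * vp
                v = v + delta
                v[pos] = w[pos] * vp
            return Bh @ v
        u = Bh.T @ x
        for pos, w in self.etas:
            val = w @ u
            u = u.copy()
            u[pos] = val
        return u

    def reconstruct(self) -> np.ndarray:
        """Dense B as represented (for diagnostics/tests): B0 E1 ... Ek."""
        M = self.B.copy()
        for pos, w in self.etas:
            col = M @ w
            M = M.copy()
            M[:, pos] = col
        return M


def factorize(B: np.ndarray, lu_factor_tol: float, ctx: ArithmeticContext,
              singularity_tol=None, max_updates: int = 100) -> LUFactors:
    """Threshold-pivoting LU; dependent columns are reported, not raised.

    When a column has no admissible pivot it is replaced (in the factorized
    copy) by a unit column and recorded in ``dependents`` as
    (basis position, pivot row); the caller then repairs the basis.
    """
    if lu_factor_tol < 1:
        raise ValueError("lu_factor_tol must be >= 1")
    m = B.shape[0]
    if B.shape != (m, m):
        raise ValueError("basis matrix must be square")
    if singularity_tol is None:
        singularity_tol = float(ctx.eps) ** (2.0 / 3.0)
    B = B.copy()
    if m == 0:
        return LUFactors(m=0, ctx=ctx, LU=ctx.zeros(0, 0), perm=[], B=B,
                         lu_factor_tol=lu_factor_tol, max_updates=max_updates)
    col_norms = [max(inf_norm(B[:, j]), 0) for j in range(m)]
    dependents: list[tuple[int, int]] = []
    while True:
        if len(dependents) > m:
            raise SingularBasisError("basis rank collapse during repair")
        W = B.copy()
        perm = list(range(m))
        failed_at = None
        for k in range(m):
            sub = W[k:, k]
            absv = np.array([abs(v) for v in sub])
            best = absv.max() if absv.size else 0
            thresh = singularity_tol * max(col_norms[k], 1e-300)
            if best <= thresh:
                failed_at = k
                break
            admissible = np.nonzero(absv >= best / lu_factor_tol)[0]
            if len(admissible) == 1:
                p = k + int(admissible[0])
            else:
                # prefer the sparsest admissible row (Markowitz-flavoured);
                # examine only the few largest candidates to stay cheap
                top = sorted(admissible, key=lambda i: -absv[i])[:4]
                nz_counts = [(sum(1 for x in W[k + i, k:] if x != 0), i)
                             for i in top]
                _, rel = min(nz_counts)
                p = k + int(rel)
            if p != k:
                W[[k, p]] = W[[p, k]]
                perm[k], perm[p] = perm[p], perm[k]
            piv = W[k, k]
            if k < m - 1:
                f = W[k + 1:, k] / piv
                W[k + 1:, k] = f
                W[k + 1:, k + 1:] = W[k + 1:, k + 1:] - np.outer(f, W[k, k + 1:])
        if failed_at is None:
            break
        # dependent column: substitute a unit column at an unpivoted row
        # and restart (dependencies are rare and bases are desk-scale).
        row = perm[failed_at]
        dependents.append((failed_at, row))
        B[:, failed_at] = ctx.zeros(m)
        B[row, failed_at] = ctx.scalar(1)
        col_norms[failed_at] = 1.0
    # recover the permutation in factorization order applied to original rows
    return LUFactors(m=m, ctx=ctx, LU=W, perm=perm, B=B,
                     lu_factor_tol=lu_factor_tol, dependents=dependents,
                     max_updates=max_updates)


def update_after_pivot(f: LUFactors, w: np.ndarray, leaving_position: int,
                       lu_update_tol: float, ctx: ArithmeticContext) -> bool:
    """Product-form update replacing basis column ``leaving_position``.

    ``w`` must be B^-1 a_entering through the *current* factors.  Returns
    False (refactor signal) when the update pivot is unstable — growth
    ||w||_inf / |w_p| beyond lu_update_tol / sqrt(eps) — or the eta file is
    full; returns True after recording the eta otherwise.
    """
    if lu_update_tol < 1:
        raise ValueError("lu_update_tol must be >= 1")
    if f.update_count >= f.max_updates:
        return False
    wp = abs(w[leaving_position])
    wmax = inf_norm(w)
    limit = lu_update_tol / float(ctx.eps) ** 0.5
    if wp == 0 or wmax / wp > limit:
        return False
    f.etas.append((leaving_position, np.asarray(w).copy()))
    return True


def repair_basis(basis: BasisState, dependents: list[tuple[int, int]],
                 form, values=None) -> tuple[BasisState, list[str]]:
    """Replace dependent basic columns by slack unit columns.

    Each dependent basis position takes the slack of its reported pivot row;
    the displaced variable leaves at its nearer finite bound.  If that slack
    is already basic the remaining unpivoted rows are tried; running out is a
    genuine rank failure.
    """
    n, m = form.n_struct, form.m
    basis = basis.copy()
    log: list[str] = []
    taken = {v - n for v in basis.basic if v >= n}
    for pos, row in dependents:
        cand_rows = [row] + [r for r in range(m)
                             if r not in taken and r != row]
        slot = next((r for r in cand_rows if r not in taken), None)
        if slot is None:
            raise SingularBasisError("basis repair exhausted unit columns")
        displaced = basis.basic[pos]
        lo, hi = form.lower[displaced], form.upper[displaced]
        if np.isinf(lo) and np.isinf(hi):
            basis.statuses[displaced] = FREE
        elif np.isinf(hi):
            basis.statuses[displaced] = AT_LOWER
        elif np.isinf(lo):
            basis.statuses[displaced] = AT_UPPER
        elif values is not None and abs(values[displaced] - hi) < abs(values[displaced] - lo):
            basis.statuses[displaced] = AT_UPPER
        else:
            basis.statuses[displaced] = AT_LOWER
        basis.basic[pos] = n + slot
        basis.statuses[n + slot] = BASIC
        taken.add(slot)
        log.append(f"basis repair: slack of row {slot} replaces "
                   f"variable {displaced} at position {pos}")
    return basis, log


def solve_with_basis(f: LUFactors, rhs, refine: int = 0) -> np.ndarray:
    return f.solve(rhs, refine=refine)


def solve_with_basis_transpose(f: LUFactors, c_B, refine: int = 0) -> np.ndarray:
    return f.solve_T(c_B, refine=refine)
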