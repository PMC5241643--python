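"""Geometric-mean row/column scaling.

Each pass replaces every row scale by the geometric mean sqrt(max * min) of
the extreme absolute entries of the (currently scaled) row, then does the
same for columns; passes stop when the spread-reduction factor between passes
exceeds 0.9 or ``max_passes`` is reached.  In the double context the final
scales are rounded to the nearest power of two so that applying and removing
them introduces no rounding whatsoever.

The scaled problem is exactly equivalent: with R = diag(r), G = diag(g) over
structural *and* slack columns, the transform is

    A_scaled = R^-1 A G^-1,   x_scaled = G x,   b_scaled = R^-1 b,
    bounds_scaled = G * bounds,   c_scaled = G^-1 c,   y_scaled = R y,

so objective values are unchanged and (un)scaling a solution is exact
arithmetic.  Unscaling a *computed* solution can still inflate primal/dual
infeasibilities measured on the original data — that hazard is why the final
certification step re-solves without scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arith import ArithmeticContext, DOUBLE
from .problem import ComputationalForm, SparseMatrix


@dataclass
class ScaleVectors:
    row_scales: np.ndarray          # r_i > 0
    col_scales: np.ndarray          # c_j > 0, structural columns only
    pass_count: int
    achieved_spread: float          # max/min of scaled |S_ij|

    def slack_scale(self, i: int) -> float:
        """Column scale of the slack of row i (keeps slack entries at -1)."""
        return 1.0 / self.row_scales[i]

    def full_col_scales(self, m: int) -> np.ndarray:
        return np.concatenate([self.col_scales, 1.0 / self.row_scales])


def _spread(vals: np.ndarray) -> float:
    return float(vals.max() / vals.min()) if vals.size else 1.0


def compute_scales(S: SparseMatrix, max_passes: int = 10,
                   ctx: ArithmeticContext = DOUBLE,
                   stop_factor: float = 0.9) -> ScaleVectors:
    """Geometric-mean scaling of the structural matrix.

    Raises on an empty matrix.  Scales are powers of two in the double
    context (documented hygiene: power-of-two scaling is exact), unrounded
    otherwise.
    """
    if S.nnz == 0:
        raise ValueError("cannot scale an empty matrix")
    rows = np.fromiter((i for i, _, _ in S.entries()), dtype=int, count=S.nnz)
    cols = np.fromiter((j for _, j, _ in S.entries()), dtype=int, count=S.nnz)
    vals = np.fromiter((abs(v) for _, _, v in S.entries()), dtype=float,
                       count=S.nnz)
    m, n = S.n_rows, S.n_cols
    logr = np.zeros(m)
    logc = np.zeros(n)
    logv = np.log2(vals)
    prev_spread = _spread(vals)
    passes = 0
    for _ in range(max_passes):
        cur = logv - logr[rows] - logc[cols]
        hi = np.full(m, -np.inf)
        lo = np.full(m, np.inf)
        np.maximum.at(hi, rows, cur)
        np.minimum.at(lo, rows, cur)
        seen = np.isfinite(hi)
        logr[seen] += 0.5 * (hi[seen] + lo[seen])
        cur = logv - logr[rows] - logc[cols]
        hi = np.full(n, -np.inf)
        lo = np.full(n, np.inf)
        np.maximum.at(hi, cols, cur)
        np.minimum.at(lo, cols, cur)
        seen = np.isfinite(hi)
        logc[seen] += 0.5 * (hi[seen] + lo[seen])
        passes += 1
        cur = logv - logr[rows] - logc[cols]
        spread = 2.0 ** float(cur.max() - cur.min())
        if spread / prev_spread > stop_factor:
            break
        prev_spread = spread
    if ctx.is_double:
        r = 2.0 ** np.rint(logr)
        c = 2.0 ** np.rint(logc)
    else:
        r = 2.0 ** logr
        c = 2.0 ** logc
    scaled = vals / (r[rows] * c[cols])
    return ScaleVectors(r, c, passes, _spread(scaled))


def apply_scaling(form: ComputationalForm, sc: ScaleVectors) -> ComputationalForm:
    """Scaled copy of a computational form (slack entries stay -1)."""
    m, n = form.m, form.n_struct
    if sc.row_scales.shape != (m,) or sc.col_scales.shape != (n,):
        raise ValueError("scale vectors do not match problem dimensions")
    if np.any(sc.row_scales <= 0) or np.any(sc.col_scales <= 0):
        raise ValueError("scales must be strictly positive")
    g = sc.full_col_scales(m)
    S2 = form.S.scaled(sc.row_scales, sc.col_scales)
    b2 = form.b / sc.row_scales
    lo2 = form.lower * g
    hi2 = form.upper * g
    c2 = form.c / g
    return ComputationalForm(S2, b2, c2, lo2, hi2, form.sense_sign,
                             form.objective_constant, list(form.row_names),
                             list(form.col_names))


def scale_solution(x, y, sc: ScaleVectors):
    """Map an original-space point into the scaled space (x_s = G x, y_s = R y)."""
    g = sc.full_col_scales(len(sc.row_scales))
    return np.asarray(x) * g, np.asarray(y) * sc.row_scales


def unscale_solution(x_scaled, y_scaled, sc: ScaleVectors):
    """Exact inverse transform: x = x_s / g, y = y_s / r.

    Exact in double arithmetic because the scales are powers of two there.
    """
    g = sc.full_col_scales(len(sc.row_scales))
    return np.asarray(x_scaled) / g, np.asarray(y_scaled) / sc.row_scales
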