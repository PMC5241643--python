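"""Problem containers: sparse matrix, LP problem, computational standard form.

The :class:`LPProblem` mirrors the flux-balance formulation

    min (or max)  c^T v   subject to   row senses on S v,   l <= v <= u,

with ``S`` an m-by-n stoichiometric (or general constraint) matrix.  The
simplex engine works on the slack ("computational") form

    min c^T x   subject to   [S  -I] x = b,   bounds on structurals + slacks,

where the slack of row i equals the row activity (S v)_i and its bounds encode
the row sense and optional range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .arith import INFINITY_THRESHOLD, ArithmeticContext, DOUBLE

#: Row senses.
EQ, LE, GE, RANGE = "E", "L", "G", "R"
_SENSES = {EQ, LE, GE, RANGE}


class SparseMatrix:
    """COO-style sparse matrix with unique (row, col) entries.

    Values are stored exactly as given (float64); promotion to a wider
    arithmetic context happens only at the point of use and is exact.
    """

    def __init__(self, n_rows: int, n_cols: int,
                 entries: Iterable[tuple[int, int, float]] = ()):
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self._data: dict[tuple[int, int], float] = {}
        for i, j, v in entries:
            self.add(i, j, v)

    def add(self, i: int, j: int, v: float, accumulate: bool = False) -> None:
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise IndexError(f"entry ({i}, {j}) outside {self.n_rows}x{self.n_cols}")
        key = (int(i), int(j))
        if key in self._data:
            if not accumulate:
                raise ValueError(f"duplicate entry at {key}")
            self._data[key] += float(v)
        else:
            self._data[key] = float(v)
        if self._data[key] == 0.0:
            del self._data[key]

    def put(self, i: int, j: int, v: float) -> None:
        """Overwrite (or delete, when v = 0) one entry."""
        key = (int(i), int(j))
        self._data.pop(key, None)
        if v != 0.0:
            self.add(i, j, v)

    @classmethod
    def from_dense(cls, M) -> "SparseMatrix":
        M = np.asarray(M, dtype=float)
        out = cls(M.shape[0], M.shape[1])
        for i in range(M.shape[0]):
            for j in range(M.shape[1]):
                if M[i, j] != 0.0:
                    out.add(i, j, M[i, j])
        return out

    # -- queries ----------------------------------------------------------
    @property
    def nnz(self) -> int:
        return len(self._data)

    def entries(self):
        """Deterministically ordered (i, j, value) triples."""
        for (i, j) in sorted(self._data):
            yield i, j, self._data[(i, j)]

    def get(self, i: int, j: int) -> float:
        return self._data.get((i, j), 0.0)

    def max_abs(self) -> float:
        return max((abs(v) for v in self._data.values()), default=0.0)

    def min_abs_nonzero(self) -> float:
        return min((abs(v) for v in self._data.values()), default=0.0)

    def columns(self) -> list[list[tuple[int, float]]]:
        cols: list[list[tuple[int, float]]] = [[] for _ in range(self.n_cols)]
        for (i, j), v in sorted(self._data.items()):
            cols[j].append((i, v))
        return cols

    def to_dense(self, ctx: ArithmeticContext = DOUBLE) -> np.ndarray:
        out = ctx.zeros(self.n_rows, self.n_cols)
        one = ctx.scalar(1)
        for (i, j), v in self._data.items():
            out[i, j] = ctx.scalar(v) if not ctx.is_double else v
        del one
        return out

    def transpose(self) -> "SparseMatrix":
        out = SparseMatrix(self.n_cols, self.n_rows)
        for (i, j), v in self._data.items():
            out.add(j, i, v)
        return out

    def scaled(self, row_scales, col_scales) -> "SparseMatrix":
        """Entrywise S_ij / (r_i c_j)."""
        out = SparseMatrix(self.n_rows, self.n_cols)
        for (i, j), v in self._data.items():
            out.add(i, j, v / (row_scales[i] * col_scales[j]))
        return out

    def matvec(self, x) -> np.ndarray:
        """S @ x in the arithmetic of the operands (context-agnostic)."""
        x = np.asarray(x)
        out = np.zeros(self.n_rows, dtype=x.dtype if x.dtype == np.float64 else object)
        if out.dtype == object:
            out[:] = [0] * self.n_rows
        for (i, j), v in self._data.items():
            out[i] = out[i] + v * x[j]
        return out

    def rmatvec(self, y) -> np.ndarray:
        """S^T @ y."""
        y = np.asarray(y)
        out = np.zeros(self.n_cols, dtype=y.dtype if y.dtype == np.float64 else object)
        if out.dtype == object:
            out[:] = [0] * self.n_cols
        for (i, j), v in self._data.items():
            out[j] = out[j] + v * y[i]
        return out

    def copy(self) -> "SparseMatrix":
        out = SparseMatrix(self.n_rows, self.n_cols)
        out._data = dict(self._data)
        return out

    def __eq__(self, other) -> bool:
        return (isinstance(other, SparseMatrix)
                and self.n_rows == other.n_rows and self.n_cols == other.n_cols
                and self._data == other._data)


class InfeasibleBoundsError(ValueError):
    """lower > upper on some column."""


@dataclass
class LPProblem:
    """A linear program over structural variables (fluxes) ``v``."""

    S: SparseMatrix
    row_sense: list[str]
    rhs: np.ndarray
    c: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)
    sense: str = "min"                       # "min" | "max"
    objective_constant: float = 0.0
    ranges: np.ndarray | None = None         # per-row range width (NaN = none)
    name: str = "LP"

    def __post_init__(self):
        m, n = self.S.n_rows, self.S.n_cols
        self.rhs = np.asarray(self.rhs, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if len(self.row_sense) != m or self.rhs.shape != (m,):
            raise ValueError("row data inconsistent with S")
        if self.c.shape != (n,) or self.lower.shape != (n,) or self.upper.shape != (n,):
            raise ValueError("column data inconsistent with S")
        for s in self.row_sense:
            if s not in _SENSES:
                raise ValueError(f"unknown row sense {s!r}")
        if self.sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        if not self.row_names:
            self.row_names = [f"R{i+1}" for i in range(m)]
        if not self.col_names:
            self.col_names = [f"C{j+1}" for j in range(n)]
        bad = [j for j in range(n) if self.lower[j] > self.upper[j]]
        if bad:
            raise InfeasibleBoundsError(
                f"lower > upper for column(s) {[self.col_names[j] for j in bad]}")

    # -- dimensions --------------------------------------------------------
    @property
    def m(self) -> int:
        return self.S.n_rows

    @property
    def n(self) -> int:
        return self.S.n_cols

    def row_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-row activity interval [rlo, rhi] implied by sense/rhs/range.

        Classical RANGES convention: a range R on an E row makes it two-sided
        ([b, b+R] for R >= 0, [b+R, b] otherwise); on an L row the interval is
        [b-|R|, b]; on a G row [b, b+|R|].
        """
        m = self.m
        rlo = np.empty(m)
        rhi = np.empty(m)
        for i, s in enumerate(self.row_sense):
            b = self.rhs[i]
            r = None
            if self.ranges is not None and not np.isnan(self.ranges[i]):
                r = self.ranges[i]
            if s == EQ:
                if r is None:
                    rlo[i] = rhi[i] = b
                elif r >= 0:
                    rlo[i], rhi[i] = b, b + r
                else:
                    rlo[i], rhi[i] = b + r, b
            elif s == LE:
                rhi[i] = b
                rlo[i] = b - abs(r) if r is not None else -np.inf
            elif s == GE:
                rlo[i] = b
                rhi[i] = b + abs(r) if r is not None else np.inf
            else:  # RANGE stored explicitly: rhs = lower, range = width
                rlo[i] = b
                rhi[i] = b + (abs(r) if r is not None else 0.0)
        return rlo, rhi

    def stats(self) -> dict:
        """Summary of dimensions and magnitude ranges (Table-style)."""
        mags = [abs(v) for _, _, v in self.S.entries()]
        finite_bounds = [abs(b) for b in list(self.lower) + list(self.upper)
                         if np.isfinite(b) and b != 0.0]
        rhs_mags = [abs(b) for b in self.rhs if b != 0.0]
        return {
            "name": self.name,
            "m": self.m,
            "n": self.n,
            "nnz": self.S.nnz,
            "max_abs_entry": max(mags, default=0.0),
            "min_abs_entry": min(mags, default=0.0),
            "coefficient_decades": (np.log10(max(mags) / min(mags))
                                    if mags else 0.0),
            "max_abs_bound": max(finite_bounds, default=0.0),
            "min_abs_bound": min(finite_bounds, default=0.0),
            "max_abs_rhs": max(rhs_mags, default=0.0),
            "min_abs_rhs": min(rhs_mags, default=0.0),
        }

    def copy(self) -> "LPProblem":
        return LPProblem(self.S.copy(), list(self.row_sense), self.rhs.copy(),
                         self.c.copy(), self.lower.copy(), self.upper.copy(),
                         list(self.row_names), list(self.col_names), self.sense,
                         self.objective_constant,
                         None if self.ranges is None else self.ranges.copy(),
                         self.name)


def problem_stats(p: LPProblem) -> dict:
    return p.stats()


@dataclass
class ComputationalForm:
    """Equality-only slack form ``[S -I] x = b`` with merged bounds.

    Columns 0..n-1 are structural, n..n+m-1 are slacks (slack i = row activity
    of row i).  ``sense_sign`` is +1 when the original problem minimizes and
    -1 when it maximizes (c here is always minimized); ``b`` is zero for
    problems converted from :class:`LPProblem` but may be general (the zoom
    strategy builds shifted forms with nonzero right-hand sides).
    """

    S: SparseMatrix
    b: np.ndarray
    c: np.ndarray                 # length n + m
    lower: np.ndarray             # length n + m
    upper: np.ndarray             # length n + m
    sense_sign: int = 1
    objective_constant: float = 0.0
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.S.n_rows

    @property
    def n_struct(self) -> int:
        return self.S.n_cols

    @property
    def n_total(self) -> int:
        return self.S.n_cols + self.S.n_rows

    def dense_A(self, ctx: ArithmeticContext) -> np.ndarray:
        """[S -I] in the requested context (exact promotion from float)."""
        m, n = self.m, self.n_struct
        A = ctx.zeros(m, n + m)
        for i, j, v in self.S.entries():
            A[i, j] = ctx.scalar(v) if not ctx.is_double else v
        neg1 = ctx.scalar(-1)
        for i in range(m):
            A[i, n + i] = neg1
        return A

    def column(self, j: int) -> list[tuple[int, float]]:
        """Sparse column j of [S -I]."""
        if j < self.n_struct:
            return [(i, v) for i, jj, v in self.S.entries() if jj == j]
        return [(j - self.n_struct, -1.0)]

    def objective_value(self, x, high=False):
        """Original-sense objective at a computational-form point."""
        acc = 0
        for cj, xj in zip(self.c, np.asarray(x)):
            if cj != 0:
                acc = acc + cj * xj
        return self.sense_sign * acc + self.objective_constant


def to_computational_form(p: LPProblem) -> ComputationalForm:
    """Convert to the slack form; maximization is negated into minimization.

    Every feasible v maps bijectively to (v, S v) in the form, and objective
    values agree after the sense/constant adjustment.
    """
    m, n = p.m, p.n
    rlo, rhi = p.row_bounds()
    lower = np.concatenate([p.lower, rlo])
    upper = np.concatenate([p.upper, rhi])
    # clamp beyond the infinity threshold
    lower[lower <= -INFINITY_THRESHOLD] = -np.inf
    upper[upper >= INFINITY_THRESHOLD] = np.inf
    sign = 1 if p.sense == "min" else -1
    c = np.concatenate([sign * p.c, np.zeros(m)])
    col_names = list(p.col_names) + [f"slack[{rn}]" for rn in p.row_names]
    return ComputationalForm(p.S.copy(), np.zeros(m), c, lower, upper,
                             sense_sign=sign,
                             objective_constant=p.objective_constant,
                             row_names=list(p.row_names), col_names=col_names)


# -- structural edits used by the ME-model layer ---------------------------

def with_extra_rows(p: LPProblem,
                    rows: Sequence[tuple[dict[int, float], str, float, str]]
                    ) -> LPProblem:
    """Return a copy of ``p`` with rows appended.

    Each row is (coeffs: {col index: value}, sense, rhs, name).
    """
    m, n = p.m, p.n
    S = SparseMatrix(m + len(rows), n)
    for i, j, v in p.S.entries():
        S.add(i, j, v)
    senses = list(p.row_sense)
    rhs = list(p.rhs)
    names = list(p.row_names)
    ranges = list(p.ranges) if p.ranges is not None else [np.nan] * m
    for k, (coeffs, sense, b, name) in enumerate(rows):
        for j, v in coeffs.items():
            if v != 0.0:
                S.add(m + k, j, v)
        senses.append(sense)
        rhs.append(b)
        names.append(name)
        ranges.append(np.nan)
    return LPProblem(S, senses, np.array(rhs), p.c.copy(), p.lower.copy(),
                     p.upper.copy(), names, list(p.col_names), p.sense,
                     p.objective_constant, np.array(ranges), p.name)


def with_extra_cols(p: LPProblem,
                    cols: Sequence[tuple[dict[int, float], float, float, float, str]]
                    ) -> LPProblem:
    """Return a copy of ``p`` with columns appended.

    Each column is (coeffs: {row index: value}, cost, lower, upper, name).
    """
    m, n = p.m, p.n
    S = SparseMatrix(m, n + len(cols))
    for i, j, v in p.S.entries():
        S.add(i, j, v)
    c = list(p.c)
    lo = list(p.lower)
    up = list(p.upper)
    names = list(p.col_names)
    for k, (coeffs, cost, l, u, name) in enumerate(cols):
        for i, v in coeffs.items():
            if v != 0.0:
                S.add(i, n + k, v)
        c.append(cost)
        lo.append(l)
        up.append(u)
        names.append(name)
    return LPProblem(S, list(p.row_sense), p.rhs.copy(), np.array(c),
                     np.array(lo), np.array(up), list(p.row_names), names,
                     p.sense, p.objective_constant,
                     None if p.ranges is None else p.ranges.copy(), p.name)
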