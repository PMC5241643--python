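"""Pluggable floating-point precision contracts.

Every numeric kernel in the package (scaling, basis factorization, simplex
pricing, residual evaluation) is written generically over numpy arrays whose
dtype is dictated by an :class:`ArithmeticContext`.  The ``double`` context
uses native ``float64``; the ``quad`` (34 decimal digits) and ``extended``
contexts use object arrays of :class:`mpmath.mpf`, so the same code path runs
at any precision.  Converting a double to a higher-precision context is exact;
the reverse rounds.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass

import numpy as np
from mpmath import mp, mpf

#: Bounds whose magnitude reaches this value are treated as absent (infinite),
#: following conventional MPS practice.
INFINITY_THRESHOLD = 1e30

_DOUBLE_EPS = float(np.finfo(np.float64).eps)


@dataclass(frozen=True)
class ArithmeticContext:
    """A named precision level plus the helpers the kernels need.

    Parameters
    ----------
    name:
        ``"double"``, ``"quad"`` or ``"extended"``.
    decimal_digits:
        Working precision in decimal digits (16 for double, 34 for quad).
    """

    name: str
    decimal_digits: int

    @property
    def is_double(self) -> bool:
        return self.name == "double"

    @property
    def dtype(self):
        return np.float64 if self.is_double else object

    @property
    def eps(self):
        """Unit roundoff of the context."""
        if self.is_double:
            return _DOUBLE_EPS
        return mpf(10) ** (1 - self.decimal_digits)

    @property
    def infinity_threshold(self) -> float:
        return INFINITY_THRESHOLD

    def workprec(self):
        """Context manager installing this precision for mpmath arithmetic.

        A no-op for the double context.  mpmath operations round to the
        precision active *at call time*, so every solver entry point wraps
        itself in ``with ctx.workprec():``.
        """
        if self.is_double:
            return contextlib.nullcontext()
        return mp.workdps(self.decimal_digits)

    def scalar(self, v):
        """Convert one number into this context (exact from float)."""
        if self.is_double:
            return float(v)
        if isinstance(v, float) and np.isinf(v):
            return mpf(v)
        return mpf(v) if not isinstance(v, mpf) else v

    def array(self, values) -> np.ndarray:
        """Copy ``values`` into a 1-D or 2-D array of this context's dtype."""
        a = np.asarray(values)
        if self.is_double:
            return a.astype(np.float64)
        out = np.empty(a.shape, dtype=object)
        flat_in = a.ravel()
        flat_out = out.ravel()
        for i, v in enumerate(flat_in):
            flat_out[i] = v if isinstance(v, mpf) else mpf(float(v))
        return out

    def zeros(self, *shape) -> np.ndarray:
        if self.is_double:
            return np.zeros(shape, dtype=np.float64)
        out = np.empty(shape, dtype=object)
        out.ravel()[:] = [mpf(0)] * out.size
        return out

    def eye(self, m) -> np.ndarray:
        out = self.zeros(m, m)
        one = self.scalar(1)
        for i in range(m):
            out[i, i] = one
        return out


DOUBLE = ArithmeticContext("double", 16)
QUAD = ArithmeticContext("quad", 34)


def extended(decimal_digits: int) -> ArithmeticContext:
    """A software context with ``decimal_digits`` of precision (>= 16)."""
    if decimal_digits < 16:
        raise ValueError("extended context needs at least 16 digits")
    return ArithmeticContext("extended", decimal_digits)


def inf_norm(v) -> float | mpf:
    """max |v_i| over finite entries; 0 for an empty vector."""
    best = 0.0
    for x in np.asarray(v).ravel():
        a = abs(x)
        if a > best:
            best = a
    return best


def to_float_array(v) -> np.ndarray:
    """Round any context's array down to float64 (lossy from quad)."""
    a = np.asarray(v)
    if a.dtype == np.float64:
        return a.copy()
    return np.array([float(x) for x in a.ravel()], dtype=np.float64).reshape(a.shape)
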