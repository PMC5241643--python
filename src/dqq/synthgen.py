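"""Seeded generation of multiscale LPs and ME-like coupled models.

Real metabolism/expression (ME) models mix stoichiometric data spanning many
orders of magnitude with flux solutions as large as 1e+8 and as small as
1e-10.  The generators here emulate those magnitudes while *planting* an
exactly feasible point, so that feasibility of every emitted instance is a
construction-time certainty rather than a numerical hope:

* every planted flux is a power of two (a "dyadic" value);
* every equality row is built from pairs of entries whose products cancel
  exactly in double arithmetic (the second entry of a pair is the first
  times a power of two), so S v0 = 0 holds with zero residual;
* inequality rows (coupling constraints) hold with a factor-2 margin and
  therefore need no exactness.

Coefficient magnitudes are log-uniform over ``coefficient_decades``; the
pairing multiplies one entry of each pair by the flux ratio, so the realized
spread of an instance can exceed the nominal decade count — instances are
reported through ``problem_stats`` and the planted point is verifiable at
50-digit precision.

All randomness flows from one ``numpy`` Generator per instance, drawn in a
fixed order, so identical specs produce bit-identical problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arith import extended
from .cobra_ext import CouplingSpec, add_coupling_constraints
from .problem import LPProblem, SparseMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated instance family."""

    m: int = 40
    n: int = 60
    density: float = 0.15
    coefficient_decades: float = 6.0    # span of log10 |S_ij| before pairing
    flux_decades: float = 6.0           # span of log10 of planted fluxes
    coupling_fraction: float = 0.2      # ME generator: couplings per n
    k_eff_low: float = 1.0e5            # effective rate constants drawn
    k_eff_high: float = 5.0e5           #   log-uniform in this window
    mu: float = 1.0                     # growth rate entering c_max = mu/k_eff
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 2 or self.n < self.m * 0 + 2:
            raise ValueError("need m >= 1 and n >= 2")
        if not (0 < self.density <= 1):
            raise ValueError("density in (0, 1]")


def _dyadic_exponents(rng, count, decades):
    """Integer exponents e with 2**e log-uniform over ``decades`` decades."""
    span_bits = decades * np.log2(10.0) / 2.0
    return rng.integers(-int(round(span_bits)), int(round(span_bits)) + 1,
                        size=count)


def generate_multiscale_lp(spec: SyntheticSpec,
                           check_digits: int = 50
                           ) -> tuple[LPProblem, np.ndarray]:
    """Sparse multiscale LP with planted exactly-feasible v0 and b = 0.

    Bounds enclose v0 with a factor-32 margin below/above (lower bound is 0
    for roughly half the columns); the objective is random with magnitudes
    inversely scaled by the planted flux so that optimal objective values
    stay O(1)-ish regardless of the flux spread.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    f = _dyadic_exponents(rng, n, spec.flux_decades)
    v0 = np.ldexp(1.0, f)                        # 2**f exactly

    S = SparseMatrix(m, n)
    all_pairs: list[tuple[int, int, int]] = []
    pairs_per_row = max(1, int(round(spec.density * n / 2.0)))
    # pair columns adjacent in flux exponent so the pairing ratio 2**(f1-f2)
    # stays O(1) and the realized coefficient spread tracks the nominal one
    order = list(np.argsort(f, kind="stable"))
    for i in range(m):
        k = min(pairs_per_row, n // 2)
        s0 = int(rng.integers(0, n - 2 * k + 1))
        window = order[s0:s0 + 2 * k]
        for t in range(k):
            j1, j2 = int(window[2 * t]), int(window[2 * t + 1])
            mag = 10.0 ** rng.uniform(-spec.coefficient_decades / 2.0,
                                      spec.coefficient_decades / 2.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            a = sign * mag
            # S[i,j1]*v0[j1] + S[i,j2]*v0[j2] = 0 exactly:
            S.add(i, j1, a, accumulate=True)
            S.add(i, j2, -np.ldexp(a, int(f[j1] - f[j2])), accumulate=True)
            all_pairs.append((i, j1, j2))
    if S.nnz == 0:
        raise ValueError("density too low to plant any structure")
    _enforce_spread(S, all_pairs, 10.0 ** spec.coefficient_decades)

    lo = np.where(rng.random(n) < 0.5, 0.0, np.ldexp(v0, -5))
    hi = np.ldexp(v0, 5)
    c = np.array([(1.0 if rng.random() < 0.5 else -1.0)
                  * 10.0 ** rng.uniform(-1, 1) * np.ldexp(1.0, -int(e))
                  for e in f])
    p = LPProblem(S, ["E"] * m, np.zeros(m), c, lo, hi,
                  name=f"multiscale-m{m}-n{n}-seed{spec.seed}")
    _assert_planted(p, v0, check_digits)
    return p, v0


def generate_me_like_model(spec: SyntheticSpec, check_digits: int = 50
                           ) -> tuple[LPProblem, CouplingSpec, np.ndarray]:
    """Block-structured metabolism+expression instance.

    A metabolic block (O(1) stoichiometry, O(1) fluxes) and an expression
    block whose "macromolecule" balance rows carry entries up to
    10**coefficient_decades against synthesis fluxes as small as the flux
    spread allows, plus coupling rows  v_use - (mu/k_eff) v_syn <= 0  tying
    catalytic usage to synthesis.  The objective maximizes the total
    synthesis (a growth-like objective).  The planted point satisfies every
    equality exactly and every coupling with a factor-2 margin.
    """
    rng = np.random.default_rng(spec.seed)
    n_met = max(2, int(round(spec.n * 0.7 / 2)) * 2)   # even
    n_exp = max(1, spec.n - n_met)
    m_met = max(1, int(round(spec.m * 0.6)))
    m_exp = max(1, spec.m - m_met)
    n = n_met + n_exp

    # planted fluxes: metabolic O(1), synthesis small
    f_met = rng.integers(-3, 4, size=n_met)
    # synthesis flux ~ usage * mu/k_eff (so couplings come out consistent)
    keff = 10.0 ** rng.uniform(np.log10(spec.k_eff_low),
                               np.log10(spec.k_eff_high), size=n_exp)
    ratio_bits = np.log2(spec.mu / keff)               # ~ -17 for 2e5
    extra = rng.integers(1, 1 + max(1, int(spec.flux_decades)), size=n_exp)
    f_exp = np.array([int(np.floor(ratio_bits[k])) - int(extra[k])
                      for k in range(n_exp)])
    f = np.concatenate([f_met, f_exp])
    v0 = np.ldexp(1.0, f)

    S = SparseMatrix(m_met + m_exp, n)
    # metabolic block: exact pair cancellation among metabolic columns
    pairs = max(1, int(round(spec.density * n_met / 2.0)))
    for i in range(m_met):
        k = min(pairs, n_met // 2)
        cols = rng.choice(n_met, size=2 * k, replace=False)
        for t in range(k):
            j1, j2 = int(cols[2 * t]), int(cols[2 * t + 1])
            a = (1.0 if rng.random() < 0.5 else -1.0) * 10.0 ** rng.uniform(-1, 1)
            S.add(i, j1, a, accumulate=True)
            S.add(i, j2, -np.ldexp(a, int(f[j1] - f[j2])), accumulate=True)
    # expression block: macromolecule rows pair a small-flux synthesis column
    # (large coefficient) against a metabolic column (small coefficient)
    for r in range(m_exp):
        i = m_met + r
        k_syn = int(rng.integers(0, n_exp))
        j_syn = n_met + k_syn
        j_met = int(rng.integers(0, n_met))
        big = 10.0 ** rng.uniform(spec.coefficient_decades - 1,
                                  spec.coefficient_decades)
        small = np.ldexp(big, int(f[j_syn] - f[j_met]))
        S.add(i, j_syn, -big, accumulate=True)     # consumes constituents
        S.add(i, j_met, small, accumulate=True)    # produced metabolically
    lo = np.zeros(n)
    hi = np.ldexp(v0, 6)
    c = np.zeros(n)
    c[n_met:] = 1.0                                # maximize total synthesis
    base = LPProblem(S, ["E"] * (m_met + m_exp), np.zeros(m_met + m_exp), c,
                     lo, hi, sense="max",
                     name=f"melike-m{spec.m}-n{spec.n}-seed{spec.seed}")
    # couplings: synthesis (small flux) bounded by (mu/k_eff) * usage,
    # i.e. row v_syn - c_max * v_use <= 0 with c_max = mu/k_eff << 1
    n_couple = max(1, int(round(spec.coupling_fraction * n_exp)))
    chosen = rng.choice(n_exp, size=min(n_couple, n_exp), replace=False)
    pairs_spec = []
    for k_syn in sorted(int(k) for k in chosen):
        j_syn = n_met + k_syn
        c_max = spec.mu / keff[k_syn]
        # usage column large enough that v0_syn <= c_max * v0_use / 2
        need_bits = f[j_syn] - int(np.floor(np.log2(c_max))) + 1
        cand = [j for j in range(n_met) if f[j] >= need_bits]
        if not cand:
            continue
        j_use = int(cand[int(rng.integers(0, len(cand)))])
        pairs_spec.append((j_syn, j_use, 0.0, c_max, keff[k_syn]))
    cspec = CouplingSpec(pairs=[(i, j, lo_, hi_) for i, j, lo_, hi_, _ in pairs_spec],
                         k_eff={(i, j): k for i, j, _, _, k in pairs_spec},
                         mu=spec.mu)
    p = add_coupling_constraints(base, cspec)
    _assert_planted(p, v0, check_digits, allow_inequality=True)
    return p, cspec, v0


def _enforce_spread(S: SparseMatrix, pairs: list[tuple[int, int, int]],
                    target: float) -> None:
    """Scale cancellation pairs by powers of two until max/min >= target.

    Scaling both members of a pair by the same power of two preserves the
    exact cancellation S[i,j1]*v0[j1] + S[i,j2]*v0[j2] = 0.
    """
    for _ in range(8):
        realized = S.max_abs() / S.min_abs_nonzero()
        if realized >= target or len(pairs) < 2:
            return
        k_up = int(np.ceil(np.log2(target / realized))) + 1
        vmin = S.min_abs_nonzero()
        # scale up a pair that does not contain the current minimum entry
        for (i, j1, j2) in pairs:
            a1, a2 = S.get(i, j1), S.get(i, j2)
            if abs(a1) != vmin and abs(a2) != vmin:
                S.put(i, j1, np.ldexp(a1, k_up))
                S.put(i, j2, np.ldexp(a2, k_up))
                break


def multiscale_suite_specs(count: int = 50, seed: int = 0,
                           max_m: int = 80) -> list[SyntheticSpec]:
    """The standard stress suite: sizes ramp to max_m x 1.5*max_m, coefficient
    spreads ramp from well-scaled to 12 decades, planted fluxes to 18 decades.
    """
    specs = []
    for i in range(count):
        frac = i / max(count - 1, 1)
        m = int(round(20 + (max_m - 20) * frac))
        n = int(round(1.5 * m))
        specs.append(SyntheticSpec(
            m=m, n=n, density=0.15,
            coefficient_decades=round(12.0 * frac, 2),
            flux_decades=round(min(18.0 * frac, 18.0), 2),
            seed=seed + i))
    return specs


def generate_degenerate_lp(seed: int, degeneracy_level: float,
                           m: int = 8, n: int = 16) -> LPProblem:
    """LP whose optimum has the given fraction of basic variables on bounds.

    A fraction ``degeneracy_level`` of the equality rows have zero right-hand
    side over nonnegative variables, so every feasible point (and in
    particular each such row's basic variable) sits exactly on its lower
    bound at the optimum; redundant parallel constraints pass through that
    vertex.  At level 0 the right-hand sides are generic and the optimum is
    nondegenerate.
    """
    if not (0 <= degeneracy_level <= 1):
        raise ValueError("degeneracy_level in [0, 1]")
    rng = np.random.default_rng(seed)
    S = SparseMatrix(m, n)
    rhs = np.zeros(m)
    senses = ["E"] * m
    c = rng.integers(1, 5, size=n).astype(float)
    lo = np.zeros(n)
    hi = np.full(n, 10.0)
    # high degeneracy embeds the cycling-prone core block (its optimum sits
    # at a massively tied vertex), so the textbook ratio test provably stalls
    embed = degeneracy_level >= 0.7 and m >= 6 and n >= 8
    row0 = col0 = 0
    if embed:
        beale = beale_cycling_lp()
        for i, j, v in beale.S.entries():
            S.add(i, j, v)
        senses[:3] = ["L", "L", "L"]
        rhs[:3] = beale.rhs
        c[:4] = beale.c
        hi[:4] = np.inf
        row0, col0 = 3, 4
    n_zero_rows = int(round(degeneracy_level * (m - row0)))
    supports = []
    for i in range(row0, m):
        k = int(rng.integers(2, 4))
        cols = sorted(int(j) for j in
                      col0 + rng.choice(n - col0, size=k, replace=False))
        supports.append(cols)
        for j in cols:
            S.add(i, j, float(rng.integers(1, 4)), accumulate=True)
    # plant a feasible integer point: columns touched by a zero row carry 0,
    # the rest small positive integers; rhs = S x0 is exact integer data
    zero_cols = {j for cols in supports[:n_zero_rows] for j in cols}
    x0 = np.zeros(n)
    for j in range(col0, n):
        if j not in zero_cols:
            x0[j] = float(rng.integers(1, 4))
    for idx, cols in enumerate(supports):
        i = row0 + idx
        rhs[i] = sum(S.get(i, j) * x0[j] for j in cols)
        if idx >= n_zero_rows:
            # non-pinning rows are inequalities: at level 0 the optimum is a
            # fully nondegenerate vertex (every row strictly slack)
            senses[i] = "L"
    return LPProblem(S, senses, rhs, c, lo, hi,
                     name=f"degenerate-{degeneracy_level}-seed{seed}")


def beale_cycling_lp() -> LPProblem:
    """The classic 3x7 degenerate LP on which the textbook ratio test cycles.

    With Dantzig pricing and lowest-index tie-breaking the plain simplex
    method revisits bases forever; the EXPAND step floor breaks the cycle.
    Optimal objective: -1/20.
    """
    M = [[0.25, -60.0, -1.0 / 25.0, 9.0],
         [0.5, -90.0, -1.0 / 50.0, 3.0],
         [0.0, 0.0, 1.0, 0.0]]
    c = np.array([-0.75, 150.0, -0.02, 6.0])
    rhs = np.array([0.0, 0.0, 1.0])
    return LPProblem(SparseMatrix.from_dense(M), ["L"] * 3, rhs, c,
                     np.zeros(4), np.full(4, np.inf), name="beale")


def generate_infeasible_lp(spec: SyntheticSpec
                           ) -> tuple[LPProblem, dict]:
    """Certified-infeasible variant of a multiscale instance.

    A singleton row pins one flux to its planted value, then the lower bound
    of that flux is raised past it; the margin is the infeasibility
    certificate.
    """
    p, v0 = generate_multiscale_lp(spec)
    rng = np.random.default_rng(spec.seed + 10_000)
    j = int(rng.integers(0, p.n))
    margin = float(np.ldexp(v0[j], 1))          # tightened bound = 4*v0 > 2*v0
    S = SparseMatrix(p.m + 1, p.n)
    for i, jj, v in p.S.entries():
        S.add(i, jj, v)
    S.add(p.m, j, 1.0)
    senses = list(p.row_sense) + ["E"]
    rhs = np.concatenate([p.rhs, [v0[j]]])
    lo = p.lower.copy()
    up = p.upper.copy()
    lo[j] = float(np.ldexp(v0[j], 2))
    up[j] = max(up[j], lo[j] * 2)
    q = LPProblem(S, senses, rhs, p.c.copy(), lo, up,
                  name=p.name + "-infeasible")
    cert = {"pinned_column": j, "pinned_value": float(v0[j]),
            "tightened_lower": float(lo[j]),
            "margin": float(lo[j] - v0[j])}
    return q, cert


def _assert_planted(p: LPProblem, v0: np.ndarray, digits: int,
                    allow_inequality: bool = False) -> None:
    """Verify the planted point at high precision; raises on failure."""
    hi = extended(max(digits, 50))
    with hi.workprec():
        vh = hi.array(v0)
        act = p.S.matvec(vh)
        rlo, rhi = p.row_bounds()
        for i in range(p.m):
            s = p.row_sense[i]
            if s == "E" and not allow_inequality:
                resid = abs(act[i] - hi.scalar(p.rhs[i]))
                if resid > hi.scalar(10) ** (-digits + 10):
                    raise AssertionError(
                        f"planted point violates row {i}: residual {resid}")
            else:
                if np.isfinite(rlo[i]) and act[i] < rlo[i]:
                    raise AssertionError(f"planted point below row {i} range")
                if np.isfinite(rhi[i]) and act[i] > rhi[i]:
                    raise AssertionError(f"planted point above row {i} range")
        for j in range(p.n):
            if v0[j] < p.lower[j] or v0[j] > p.upper[j]:
                raise AssertionError(f"planted point outside bounds of col {j}")


def planted_residual(p: LPProblem, v0, digits: int = 50):
    """max |S v0 - b| over equality rows at ``digits`` precision."""
    hi = extended(digits)
    with hi.workprec():
        act = p.S.matvec(hi.array(v0))
        worst = hi.scalar(0)
        for i in range(p.m):
            if p.row_sense[i] == "E":
                r = abs(act[i] - hi.scalar(p.rhs[i]))
                if r > worst:
                    worst = r
        return worst
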