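"""Refine a double-precision solution by repeated zooms.

Solves an 8-decade instance with the plain double simplex (tolerances
1e-9), then runs zoom rounds: residuals r = b - Ax and d = c - A^T y are
computed at 32, 64, ... digits, magnified into a well-scaled correction
problem, and re-solved with the same double solver.  Each round shrinks
max(Pinf, Dinf) by many orders of magnitude — high accuracy from a
fixed-precision inner solver.
"""

from dqq import (SolverOptions, SyntheticSpec, generate_multiscale_lp,
                 primal_simplex, to_computational_form, zoom_refine)

opts = SolverOptions(feasibility_tol=1e-9, optimality_tol=1e-9,
                     expand_frequency=100000, lu_factor_tol=5.0,
                     lu_update_tol=5.0)
problem, _ = generate_multiscale_lp(
    SyntheticSpec(m=15, n=24, coefficient_decades=8, flux_decades=8, seed=13))
form = to_computational_form(problem)

first = primal_simplex(form, opts)
print(f"double solve: {first.status}, "
      f"max(Pinf, Dinf) = {max(float(first.Pinf), float(first.Dinf)):.2e}")

state = zoom_refine(form, first.v, first.y, opts, first.basis,
                    rounds_max=4, target_tol=1e-40)
for rd in state.rounds:
    print(f"  round {rd['round']}: residuals at {rd['residual_digits']} "
          f"digits, sigma {rd['sigma']:.1e}, max(Pinf, Dinf) -> "
          f"{rd['max_pd']:.2e}")
print(f"converged to 1e-40 (relative): {state.converged}")
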