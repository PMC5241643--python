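# Methods

## Problem form and computational representation

The package solves linear programs `min c^T v, S v {=,≤,≥,range} b, l ≤ v ≤ u`
(maximization is stored as a sense flag and negated internally).  All
solving happens on the equality-only slack form `[S −I] x = 0` in which the
slack of row *i* equals the row activity and carries the row's
sense/range as bounds.  The right-hand side of the slack form is general
(the zoom strategy builds shifted forms with nonzero `b`).  MPS input is
parsed at full double precision, in either the fixed 12-character-field
layout or a whitespace-tokenized free dialect; bounds at or beyond 1e+30
are treated as absent.

## Arithmetic contexts

Every numeric kernel is written over numpy arrays whose dtype comes from an
arithmetic context: native float64 ("double", 16 digits), or object arrays
of mpmath floats for "quad" (34 digits) and "extended" (any digit count;
residual evaluation and certification use ≥ 50).  Promotion double→quad is
exact; all mpmath operations run inside an explicit working-precision
scope.  There are no hidden native-precision shortcuts in the quad path:
the identical simplex/LU code executes in either context.

## Basis linear algebra

The basis `B` is factorized densely (desk-scale bases) by Gaussian
elimination with threshold partial pivoting: a pivot must be within a
factor `lu_factor_tol` of its column maximum, and among admissible
candidates the sparsest row wins (the stability/sparsity trade the factor
tolerance names).  Columns whose best pivot falls below
`eps^(2/3) · ‖column‖` are *reported* as dependent rather than raised; the
caller repairs the basis by making the corresponding rows' slack variables
basic (the displaced variable leaves at its nearer bound) and refactorizes.
The `eps^(2/3)` constant is this package's choice of near-singularity
threshold; it reproduces the qualitative behavior that ill-conditioned
multiscale bases look singular in double but factor cleanly in quad.

After each pivot the factors are updated in **product form** (the solved
entering column is kept as an eta vector).  Product form was chosen over
spike-elimination updates for simplicity and precision-genericity; the
contract that matters — solves through updated factors agree with a fresh
factorization — is property-tested.  An update is refused (refactorization
signal) when the eta pivot satisfies `‖w‖∞ / |w_p| > lu_update_tol / √eps`
or the eta file reaches `refactor_frequency` (default 100 iterations).
Every basis solve optionally takes iterative-refinement passes with the
residual computed at twice the working digits.

## Revised primal simplex

Phases 1 and 2 share one cycle: factorize/update, `B^T y = c_B`, price
`z_N = c_N − N^T y` (Dantzig: most violating reduced cost; entering ties
break toward the lowest index for reproducibility), `B d = a_q`, EXPAND
ratio test, pivot (or bound flip for boxed variables).  Phase 1 minimizes
the sum of bound infeasibilities using the infeasibility gradient of the
basic variables as the cost vector.

**Tolerances.** Feasibility tolerances are applied *per variable*, scaled
by `1 + |bound|`.  An earlier design scaled them by a global `1 + ‖x_B‖∞`;
on 12-decade instances that scale oscillates with the iterate and the
solver can flip between phases indefinitely — a failure mode found during
development and eliminated by the per-bound convention.  Phase
classification always uses the full `δ1` while the EXPAND working
tolerance breathes between `δ1/2` and `δ1`.  The optimality test uses
`δ2 · (1 + ‖y‖∞)`; an absolute variant (`δ2` alone) exists for the zoomed
problems of iterative refinement, which are constructed so that dual
violations are O(1).  The certified quantities `Pinf ≤ δ1(1+‖v‖∞)`,
`Dinf ≤ δ2(1+‖y‖∞)` are recomputed on the data as solved in ≥ 50-digit
arithmetic, never taken from working quantities.

**EXPAND.** The working feasibility tolerance grows by
`(δ1 − δ1/2)/expand_frequency` per iteration; the ratio test first finds
the largest step allowed when every blocking bound is relaxed by the
post-iteration tolerance, then picks the largest-|pivot| blocker within
that step, and the step is never shorter than `increment/|pivot|` — so a
positive step exists even at a fully degenerate vertex.  Every
`expand_frequency` iterations (and at optimality claims) the tolerance
resets to `δ1/2`, the basis is refactorized, and basic values are
recomputed.  A `classic_ratio_test` option disables the step floor
(textbook minimum ratio, lowest-index tie-break); it exists to demonstrate
cycling and is exercised by the tests on the classic 3×4 cycling LP and on
generated high-degeneracy instances, where it provably stalls while EXPAND
terminates.

Iterations whose step is at the EXPAND floor are counted as degenerate.
Unboundedness returns a ray certificate; infeasibility is declared only
after cleanup refactorizations confirm phase-1 stationarity.

## Scaling

Geometric-mean scaling: each pass sets every row scale to
`sqrt(max·min)` of the scaled absolute row entries, then columns likewise;
passes stop when the spread-reduction factor exceeds 0.9 (configurable) or
after 10 passes.  In the double context the final scales are rounded to
powers of two, making apply/unapply exact; slack columns carry scale
`1/r_i` so their entries stay −1.  The transform keeps the objective value
identical and maps duals by `y → R y`.

## The three-step procedure

Step D solves the scaled problem in double with tolerances 1e-7, expand
frequency 100000 and LU tolerances 1.9/1.9, under an iteration limit
(default `5(m+n)`; a truncated D simply hands Q1 more work).  Step Q1
re-solves the same scaled problem in quad at 1e-15 with LU tolerances
10/10, warm-started from D's final statuses; basic values are *recomputed*
in quad rather than copied, so no double rounding is embedded.  Step Q2
re-solves the unscaled problem in quad at 1e-15 with LU tolerances 5/5,
warm-started from Q1.  Per-step reports carry the objective and the
50-digit Pinf/Dinf on original data, rendered also as floor-log10 cells
("—" for exact zero).  A note is emitted when the D and Q2 objectives
disagree in their leading digits, and D-step infeasibility claims are
only reported after quad confirms them.

## Formulation layer

*Coupling constraints.* A ratio bound `c_min ≤ v_i/v_j ≤ c_max` on
nonnegative fluxes becomes `v_i − c_max v_j ≤ 0` and `−v_i + c_min v_j ≤ 0`
(the second omitted when `c_min = 0`).  Growth-dependent ceilings are
recorded as `c_max = μ/k_eff`.

*Lifting.* Entries with `|K| > τ` are split through an auxiliary variable
(`√|K|·v_j − w = 0`, the entry becomes `sign(K)√|K|` on `w`), repeated
until the largest entry is ≤ τ.  The per-entry √-split is this package's
scheme; its justification is the tested invariant that lifted and original
optima agree to 1e-20 relative under the quad pipeline.

*Consistency screening.* Stoichiometric consistency (existence of strictly
positive molecular masses `ℓ` with `S^T ℓ = 0`) is screened through the
linear relaxation `max Σz` s.t. `S^T ℓ = 0, z ≤ ℓ, 0 ≤ z ≤ α, 0 ≤ ℓ ≤ β`
(defaults α = 1e-4, β = 1e4); rows with `ℓ_i < α` are flagged.  The
relaxation direction (maximize the count of rows that can carry at least α
of mass) is an interpretive choice; the flag set is validated against
brute-force search on small networks.

*FVA.* After the base solve (optimum `Z0`), each requested flux is
minimized and maximized under `c^T v ≥ γ Z0` (mirrored for minimization
problems).  Solves run min-then-max, index-ascending, each warm-started
from the previous basis; the appended objective row's slack starts basic,
so the first warm start is a valid `m+1` basis.  Tolerance-level
`min > max` inversions at pinned fluxes are snapped to their midpoint.

*Growth bisection.* `builder(μ)` gives the LP at fixed μ.  Exactly one
interval endpoint may be feasible: the classical orientation (feasible at
`μ_lo`, growth demands eventually infeasible) returns the largest feasible
μ; the reverse orientation (capacity couplings relax with μ) returns the
smallest.  Each test is a phase-1 solve warm-started from the previous
basis, quad by default so near-threshold tests are decided reliably.

## Zoom refinement

Round structure: residuals `r = b − Ax1`, `d = c − A^T y1` at elevated
precision (32 digits, doubling each round); magnification
`σ = 1/max(‖r‖∞, worst dual sign violation, tiny)` capped at 1e9 per
round; zoomed problem `min (σd)^T x̂, A x̂ = σr,
σ(l−x1) ≤ x̂ ≤ σ(u−x1)`, solved warm-started (scaled when the inner solver
is double, priced with the absolute optimality tolerance); corrections
`x = x1 + x̂/σ, y = y1 + ŷ/σ`.  Two findings shaped the σ rule: the dual
part must include *sign violations at nonbasic columns* (after a double
solve these dominate, and a σ driven by the tiny primal residual alone
produces zoomed problems outside double range), and capping σ at 1e9
bounds each round's magnification to what the inner solver can absorb —
repeated rounds provide the rest.  The trace of max(Pinf, Dinf) must
decrease strictly; a non-decreasing round stops the process with the best
point kept and a stagnation flag.

## Synthetic instances

The generators plant *exactly* feasible points rather than approximately
feasible ones: planted fluxes are powers of two, and every equality row is
assembled from entry pairs `(a, −a·2^(f1−f2))` whose products against the
planted fluxes cancel exactly in double arithmetic (power-of-two scaling
is exact), so `S v0 = 0` holds with zero residual — verifiable at 50-digit
precision.  Columns are paired adjacently in flux exponent so the pairing
factor stays O(1) and the realized coefficient spread tracks the nominal
decade count; one cancellation pair is power-of-two rescaled when needed
to guarantee the nominal spread is reached.  Bounds enclose the planted
point with a factor-32 margin; objective magnitudes are inversely scaled
by the planted flux so optimal values stay moderate.

The ME-like family adds an expression block (large coefficients, up to
`10^decades`, against synthesis fluxes planted near `μ/k_eff` of their
usage fluxes) and coupling rows `v_syn ≤ (μ/k_eff)v_use` with `k_eff`
log-uniform in [1e5, 5e5] — inequalities hold with a factor-2 margin and
need no exactness.  The degenerate family plants a feasible integer point,
pins a `level` fraction of rows to zero right-hand sides (their variables
sit exactly on bounds at every feasible point), and, at level ≥ 0.7,
embeds the classic cycling LP block so that stalling of the textbook ratio
test is structural, not accidental.  The infeasible family pins one flux
by a singleton equality row and then raises that flux's lower bound past
the pinned value; the margin is the certificate.  All randomness flows
from one seeded generator per instance in a fixed draw order, so identical
specs are byte-identical.

What the generators do *not* emulate: biological network topology (no
reaction/pathway structure beyond block sparsity), curated biomass
compositions, or the extreme dimensions of genome-scale reconstructions
(suite instances stay ≤ 80×120 so the full pipeline runs in seconds per
instance in software quad arithmetic).  Passing the suite therefore
demonstrates numerical behavior under the stated magnitude regimes, not
biological fidelity at genome scale.

## Verification tiers

Ground truth comes in three tiers: (1) exhaustive basic-solution
enumeration, in float for screening and in exact rational arithmetic for
quad-level comparisons, on instances with ≤ ~10 rows+columns; (2) planted
constructions (exact feasibility, planted thresholds, certified
infeasibility margins); (3) cross-method agreement (scaled vs unscaled,
warm vs cold, lifted vs original, zoom vs quad).  The oracle test family
uses integer data throughout so that distinct vertex objectives are
separated by ≥ ~1e-6 and a 1e-25 agreement check is meaningful.

## Sizes and defaults

Default suite: 50 instances ramping from 20×30 well-scaled to 80×120 with
12-decade coefficients and 18-decade planted fluxes — the magnitude regime
of genome-scale ME models at sizes where the full three-step pipeline,
including 50-digit certification, completes in a few seconds per instance.
Key defaults: refactorization every 100 iterations; D-step iteration limit
`5(m+n)`; EXPAND frequency 100000 in all production steps; singularity
threshold `eps^(2/3)`; zoom residuals from 32 digits doubling per round,
σ cap 1e9.  Wall-clock times are recorded in reports but never part of any
assertion.

## Known limitations

Dense LU (no supernodal/blocked kernels) limits practical bases to a few
hundred rows; Dantzig pricing (no steepest edge) can need many iterations
on massively degenerate problems, as the degenerate family shows; the
consistency relaxation is a screen, not a certificate of inconsistency;
rational/exact arithmetic is used only as a test oracle, never as a
solution path.
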