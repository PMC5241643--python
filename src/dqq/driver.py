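"""The Double-Quad-Quad (DQQ) driver.

Step D  solves the geometrically scaled problem with the double-precision
        simplex under fairly strict options (feasibility/optimality 1e-7).
Step Q1 warm-starts the 34-digit quad simplex on the same scaled problem
        with 1e-15 tolerances; statuses carry over verbatim and basic values
        are recomputed in quad from the factorized basis (copying the double
        values would embed their rounding).
Step Q2 warm-starts quad again on the *unscaled* data, also at 1e-15, so the
        final tolerances apply to the original problem — unscaling a scaled
        solution can otherwise inflate its primal/dual infeasibilities.

Each step's report carries the objective and the primal/dual infeasibilities
(Pinf, Dinf) of its unscaled solution measured on the original data in
>= 50-digit arithmetic, in absolute form and as the log10 cells the result
tables use ("—" for an exact zero).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .arith import DOUBLE, QUAD, to_float_array
from .linalg import BasisState
from .problem import ComputationalForm, LPProblem, to_computational_form
from .scaling import apply_scaling, compute_scales, unscale_solution
from .simplex import (INFEASIBLE, OPTIMAL, SimplexResult, SolverOptions,
                      compute_infeasibilities, primal_simplex)

STEPS = ("D", "Q1", "Q2")


def default_options(step: str) -> SolverOptions:
    """Preferred runtime options for each step (plus the solver defaults).

    D:  double, scaled, tolerances 1e-7, expand 100000, LU tols 1.9/1.9.
    Q1: quad, scaled, tolerances 1e-15, expand 100000, LU tols 10/10.
    Q2: quad, unscaled, tolerances 1e-15, expand 100000, LU tols 5/5.
    ``default_options("default")`` returns the plain double defaults
    (1e-6, expand 10000, LU 100/10).
    """
    if step == "D":
        return SolverOptions(scale=True, feasibility_tol=1e-7,
                             optimality_tol=1e-7, expand_frequency=100000,
                             lu_factor_tol=1.9, lu_update_tol=1.9, ctx=DOUBLE)
    if step == "Q1":
        return SolverOptions(scale=True, feasibility_tol=1e-15,
                             optimality_tol=1e-15, expand_frequency=100000,
                             lu_factor_tol=10.0, lu_update_tol=10.0, ctx=QUAD)
    if step == "Q2":
        return SolverOptions(scale=False, feasibility_tol=1e-15,
                             optimality_tol=1e-15, expand_frequency=100000,
                             lu_factor_tol=5.0, lu_update_tol=5.0, ctx=QUAD)
    if step == "default":
        return SolverOptions()
    raise ValueError(f"unknown step {step!r}")


def log10_cell(value) -> str:
    """Result-table rendering: exact zero -> '—', else signed floor log10."""
    v = abs(float(value))
    if v == 0.0:
        return "—"
    e = math.floor(math.log10(v))
    return f"{e:+03d}".replace("+", "+") if e >= 0 else str(e)


@dataclass
class StepReport:
    step: str
    status: str
    iterations: int
    wall_time: float
    objective: float
    Pinf: float                   # on original unscaled data, >= 50 digits
    Dinf: float
    degenerate_iterations: int = 0
    basis_repairs: int = 0

    @property
    def pinf_cell(self) -> str:
        return log10_cell(self.Pinf)

    @property
    def dinf_cell(self) -> str:
        return log10_cell(self.Dinf)

    def to_dict(self) -> dict:
        return {"step": self.step, "status": self.status,
                "iterations": self.iterations,
                "wall_time": round(self.wall_time, 3),
                "objective": self.objective,
                "Pinf": float(self.Pinf), "Dinf": float(self.Dinf),
                "Pinf_log10": self.pinf_cell, "Dinf_log10": self.dinf_cell,
                "degenerate_iterations": self.degenerate_iterations,
                "basis_repairs": self.basis_repairs}


@dataclass
class DQQReport:
    problem_name: str
    status: str                   # final (step Q2) status, quad-certified
    steps: list[StepReport]
    v: np.ndarray                 # structural fluxes, original units (float)
    y: np.ndarray                 # row duals, original units (float)
    z: np.ndarray                 # reduced costs c - S^T y (float)
    objective: float
    Pinf: float                   # final, >= 50-digit measurement
    Dinf: float
    v_norm: float
    y_norm: float
    problem_stats: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    total_time: float = 0.0
    basis: BasisState | None = None

    def certified(self, tol: float = 1e-15) -> bool:
        return (self.status == OPTIMAL
                and float(self.Pinf) <= tol * (1 + self.v_norm)
                and float(self.Dinf) <= tol * (1 + self.y_norm))

    def table(self) -> str:
        """Three-line per-problem block: Itns, Times, objective, Pinf, Dinf."""
        lines = [f"{'step':>4} {'itns':>8} {'time':>8} "
                 f"{'objective':>20} {'Pinf':>5} {'Dinf':>5}"]
        for s in self.steps:
            lines.append(f"{s.step:>4} {s.iterations:>8} {s.wall_time:>8.1f} "
                         f"{s.objective:>20.10e} {s.pinf_cell:>5} {s.dinf_cell:>5}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"problem": self.problem_name, "status": self.status,
                "objective": self.objective,
                "Pinf": float(self.Pinf), "Dinf": float(self.Dinf),
                "Pinf_log10": log10_cell(self.Pinf),
                "Dinf_log10": log10_cell(self.Dinf),
                "v_norm": self.v_norm, "y_norm": self.y_norm,
                "steps": [s.to_dict() for s in self.steps],
                "problem_stats": self.problem_stats, "notes": self.notes,
                "total_time": round(self.total_time, 3)}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def certify(form: ComputationalForm, x, y, basis: BasisState,
            dps: int = 50) -> dict:
    """Recompute Pinf/Dinf on the original data at >= 50 digits."""
    pinf, dinf = compute_infeasibilities(form, x, y, basis.statuses, dps=dps)
    return {"Pinf": pinf, "Dinf": dinf,
            "Pinf_log10": log10_cell(pinf), "Dinf_log10": log10_cell(dinf)}


def run_dqq(p: LPProblem, overrides: dict[str, SolverOptions] | None = None,
            d_iteration_limit: int | None = None,
            scale_passes: int = 10, start: BasisState | None = None) -> DQQReport:
    """Run the three-step procedure on an LP.

    ``overrides`` may supply a full :class:`SolverOptions` per step name.
    ``d_iteration_limit`` truncates step D (default 5*(m+n)): on problems
    where double precision struggles, Q1 takes over the remaining work.
    """
    t_start = time.time()
    overrides = overrides or {}
    form = to_computational_form(p)
    m, n = form.m, form.n_struct

    opts_d = overrides.get("D", default_options("D"))
    opts_q1 = overrides.get("Q1", default_options("Q1"))
    opts_q2 = overrides.get("Q2", default_options("Q2"))
    if d_iteration_limit is None:
        d_iteration_limit = 5 * (m + n)
    if opts_d.iteration_limit is None:
        from dataclasses import replace
        opts_d = replace(opts_d, iteration_limit=d_iteration_limit)

    notes: list[str] = []
    use_scaling = opts_d.scale and form.S.nnz > 0
    if use_scaling:
        sc = compute_scales(form.S, max_passes=scale_passes, ctx=DOUBLE)
        scaled = apply_scaling(form, sc)
    else:
        sc = None
        scaled = form

    steps: list[StepReport] = []

    def original_point(res: SimplexResult, scaled_space: bool):
        if scaled_space and sc is not None:
            return unscale_solution(to_float_array(res.v),
                                    to_float_array(res.y), sc)
        return res.v, res.y

    def report_step(name, res, scaled_space):
        x0, y0 = original_point(res, scaled_space)
        pinf, dinf = compute_infeasibilities(form, x0, y0,
                                             res.basis.statuses, dps=50)
        steps.append(StepReport(name, res.status, res.iterations,
                                res.wall_time, res.objective, pinf, dinf,
                                res.degenerate_iterations, res.basis_repairs))

    # -- step D -----------------------------------------------------------
    res_d = primal_simplex(scaled, opts_d, start)
    report_step("D", res_d, scaled_space=True)
    if res_d.status == "iteration_limit":
        notes.append(f"step D hit its iteration limit ({opts_d.iteration_limit}); "
                     "steps Q1/Q2 complete the solve")
    warm = res_d.basis if res_d.status != "numeric_error" else None
    if warm is None:
        notes.append("step D failed numerically; Q1 cold-starts from the "
                     "slack basis")

    # -- step Q1 ----------------------------------------------------------
    res_q1 = primal_simplex(scaled, opts_q1, warm)
    report_step("Q1", res_q1, scaled_space=True)

    # -- step Q2 ----------------------------------------------------------
    res_q2 = primal_simplex(form, opts_q2, res_q1.basis)
    report_step("Q2", res_q2, scaled_space=False)

    if (steps[0].status == OPTIMAL and steps[2].status == OPTIMAL
            and not _leading_digits_agree(steps[0].objective,
                                          steps[2].objective, 1)):
        notes.append("double (D) and quad (Q2) objectives disagree in their "
                     "leading digits: double precision alone is unreliable "
                     "on this problem")
    if res_q2.status == INFEASIBLE:
        notes.append("infeasibility certified by the quad phase-1 solve")

    x_fin = to_float_array(res_q2.v)
    y_fin = to_float_array(res_q2.y)
    z_fin = to_float_array(res_q2.z)
    report = DQQReport(
        problem_name=p.name, status=res_q2.status, steps=steps,
        v=x_fin[:n], y=y_fin, z=z_fin[:n], objective=res_q2.objective,
        Pinf=steps[2].Pinf, Dinf=steps[2].Dinf,
        v_norm=float(np.max(np.abs(x_fin[:n])) if n else 0.0),
        y_norm=float(np.max(np.abs(y_fin)) if m else 0.0),
        problem_stats=p.stats(), notes=notes,
        total_time=time.time() - t_start, basis=res_q2.basis)
    return report


def _leading_digits_agree(a: float, b: float, digits: int) -> bool:
    if a == b:
        return True
    if a == 0 or b == 0 or (a > 0) != (b > 0):
        return False
    return abs(a - b) <= abs(b) * 10.0 ** (-digits)
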