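"""Integer linear program for the transfer-planning problem.

Variables: one continuous LWT >= 0 and one integer npp per doctor.
Constraints, per doctor i with booked count b_i, cap wt_i:

* cap:          (et+dt)*b_i + et*npp_i <= wt_i
* LWT bound:    (et+dt)*b_i + et*npp_i <= LWT
* conservation: sum_i npp_i = 0
* sign/bounds:  a sender has npp_i in [-b_i, 0], a receiver npp_i >= 0
                (its upper bound is implied by the cap and LWT rows)

Objective: minimize LWT.  The model is built symbolically as a
:class:`ModelSpec` and handed to a pluggable solver; HiGHS (through
``scipy.optimize.milp``) is the registered backend.  LWT is declared
continuous but is integral at the optimum for integer data, since the
minimized LWT equals the largest post-plan workload, an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .instance import (
    Backend,
    ClinicInstance,
    Mode,
    SolveResult,
    Status,
    TransferPlan,
    post_workload,
    transfer_roles,
    validate_instance,
)


class SolverUnavailableError(RuntimeError):
    """Raised when the requested MILP solver is not installed."""


class SolverTimeoutError(RuntimeError):
    """Raised when the MILP solver hits its time limit before optimality."""


@dataclass(frozen=True)
class LinearRow:
    """One linear constraint lb <= coeffs . x <= ub over [LWT, npp...]."""

    name: str
    coeffs: tuple[float, ...]
    lb: float
    ub: float


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic ILP: variables, bounds, integrality, rows and objective."""

    instance: ClinicInstance
    mode: Mode
    variable_names: tuple[str, ...]
    objective: tuple[float, ...]
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]
    integrality: tuple[int, ...]
    rows: tuple[LinearRow, ...] = field(repr=False)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def n_constraints(self) -> int:
        return len(self.rows)

    def to_lp(self) -> str:
        """Render in LP text format for inspection/debugging."""

        def term(c, name):
            sign = "+" if c >= 0 else "-"
            return f"{sign} {abs(c):g} {name}"

        lines = ["Minimize", " obj: " + " ".join(
            term(c, n) for c, n in zip(self.objective, self.variable_names) if c)]
        lines.append("Subject To")
        for row in self.rows:
            expr = " ".join(term(c, n) for c, n in
                            zip(row.coeffs, self.variable_names) if c)
            if row.lb == row.ub:
                lines.append(f" {row.name}: {expr} = {row.lb:g}")
            else:
                if row.ub != math.inf:
                    lines.append(f" {row.name}: {expr} <= {row.ub:g}")
                if row.lb != -math.inf:
                    lines.append(f" {row.name}_lo: {expr} >= {row.lb:g}")
        lines.append("Bounds")
        for lo, hi, name in zip(self.lower_bounds, self.upper_bounds,
                                self.variable_names):
            lo_s = f"{lo:g}" if lo != -math.inf else "-inf"
            hi_s = f"{hi:g}" if hi != math.inf else "+inf"
            lines.append(f" {lo_s} <= {name} <= {hi_s}")
        lines.append("General")
        lines.append(" " + " ".join(
            n for n, z in zip(self.variable_names, self.integrality) if z))
        lines.append("End")
        return "\n".join(lines) + "\n"


def build_model(instance: ClinicInstance, mode: Mode | str = Mode.LEAN) -> ModelSpec:
    """Assemble the ILP for an instance under the given sign-constraint mode."""
    mode = Mode(mode)
    violations = validate_instance(instance)
    if violations:
        raise ValueError("invalid instance: " + "; ".join(violations))
    td = instance.td
    st, et = instance.service_time, instance.et
    roles = transfer_roles(instance, mode)

    names = ("LWT",) + tuple(f"npp_{i}" for i in range(td))
    objective = (1.0,) + (0.0,) * td
    integrality = (0,) + (1,) * td
    lower = [0.0]
    upper = [math.inf]
    for i, role in enumerate(roles):
        b = instance.doctors[i].booked
        if role == "send":
            lower.append(float(-b))
            upper.append(0.0)
        else:
            lower.append(0.0)
            upper.append(math.inf)

    rows: list[LinearRow] = []
    for i, d in enumerate(instance.doctors):
        coeffs = [0.0] * (td + 1)
        coeffs[1 + i] = float(et)
        rows.append(LinearRow(f"cap_{i}", tuple(coeffs), -math.inf,
                              float(d.work_time - st * d.booked)))
    for i, d in enumerate(instance.doctors):
        coeffs = [0.0] * (td + 1)
        coeffs[0] = -1.0
        coeffs[1 + i] = float(et)
        rows.append(LinearRow(f"lwt_{i}", tuple(coeffs), -math.inf,
                              float(-st * d.booked)))
    rows.append(LinearRow("conservation", (0.0,) + (1.0,) * td, 0.0, 0.0))

    return ModelSpec(instance=instance, mode=mode, variable_names=names,
                     objective=objective, lower_bounds=tuple(lower),
                     upper_bounds=tuple(upper), integrality=integrality,
                     rows=tuple(rows))


def _solve_highs(model: ModelSpec, time_limit: float | None) -> SolveResult:
    from scipy.optimize import Bounds, LinearConstraint, milp

    A = np.array([row.coeffs for row in model.rows], dtype=float)
    constraints = LinearConstraint(
        A,
        lb=np.array([row.lb for row in model.rows]),
        ub=np.array([row.ub for row in model.rows]),
    )
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=np.array(model.objective),
        integrality=np.array(model.integrality),
        bounds=Bounds(np.array(model.lower_bounds), np.array(model.upper_bounds)),
        constraints=constraints,
        options=options,
    )
    if res.status == 2:  # infeasible
        return SolveResult(lwt=None, plan=None, mode=model.mode,
                           backend=Backend.MILP, status=Status.INFEASIBLE)
    if res.status == 1:
        raise SolverTimeoutError(
            f"HiGHS hit its limit before proving optimality: {res.message}")
    if not res.success:
        raise RuntimeError(f"HiGHS failed: {res.message}")
    npp = tuple(int(round(x)) for x in res.x[1:])
    if any(abs(x - n) > 1e-6 for x, n in zip(res.x[1:], npp)):
        raise RuntimeError("solver returned non-integral transfer counts")
    plan = TransferPlan(npp)
    # optimal LWT equals the max post-plan workload; recomputing it from the
    # integral plan removes any floating-point residue
    lwt = max(post_workload(model.instance, plan, i)
              for i in range(model.instance.td))
    if abs(res.x[0] - lwt) > 1e-6:
        raise RuntimeError(f"solver LWT {res.x[0]} inconsistent with plan "
                           f"workloads (max {lwt})")
    return SolveResult(lwt=lwt, plan=plan, mode=model.mode,
                       backend=Backend.MILP, status=Status.OPTIMAL)


_SOLVERS = {"highs": _solve_highs}


def solve_milp(model: ModelSpec, solver_choice: str = "highs",
               time_limit: float | None = None) -> SolveResult:
    """Solve a built model through the named MILP solver.

    ``highs`` (SciPy's bundled HiGHS) is the supported backend; asking for
    an uninstalled solver raises :class:`SolverUnavailableError` with an
    install hint.
    """
    key = solver_choice.lower()
    if key not in _SOLVERS:
        raise SolverUnavailableError(
            f"MILP solver {solver_choice!r} is not available; supported: "
            f"{sorted(_SOLVERS)}. Install the corresponding package (e.g. "
            f"'pip install {solver_choice}') or use solver_choice='highs'.")
    return _SOLVERS[key](model, time_limit)
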