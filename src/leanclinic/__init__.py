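"""Outpatient capacity planning by min-max workload leveling.

Outpatient service is split, lean-style, into an examination stage (chief
complaint plus first medical order) and a diagnosis stage (reading results,
treatment plan).  Examination services booked with overloaded senior doctors
are reallocated to associate senior doctors so that the largest per-doctor
working time (LWT) is minimized, subject to per-doctor working-time caps and
conservation of the total number of transferred services.

The optimizer comes in two interchangeable backends: a solver-free exact
binary search (:mod:`leanclinic.exact`) and an integer linear program solved
through HiGHS (:mod:`leanclinic.milp`).
"""

from .instance import (
    Backend,
    ClinicInstance,
    DoctorRecord,
    Mode,
    Rank,
    SolveResult,
    Status,
    TransferPlan,
    base_workload,
    check_plan,
    post_workload,
    validate_instance,
)
from .exact import FeasibilityCertificate, feasible_at, solve_exact, canonical_plan
from .milp import ModelSpec, build_model, solve_milp
from .metrics import MetricsReport, before_after_table, compute_metrics, rts, rtds
from .generate import expand_matrix, random_instance, table2_row, table4_scenario

__version__ = "0.1.0"


def solve(instance: ClinicInstance, mode: Mode | str = Mode.LEAN,
          backend: Backend | str = Backend.EXACT, solver: str = "highs") -> SolveResult:
    """Solve an instance with the chosen backend (exact binary search or MILP)."""
    backend = Backend(backend)
    mode = Mode(mode)
    if backend is Backend.EXACT:
        return solve_exact(instance, mode)
    return solve_milp(build_model(instance, mode), solver)


__all__ = [
    "Backend", "ClinicInstance", "DoctorRecord", "FeasibilityCertificate",
    "MetricsReport", "Mode", "ModelSpec", "Rank", "SolveResult", "Status",
    "TransferPlan", "base_workload", "before_after_table", "build_model",
    "canonical_plan", "check_plan", "compute_metrics", "expand_matrix",
    "feasible_at", "post_workload", "random_instance", "rts", "rtds",
    "solve", "solve_exact", "solve_milp", "table2_row", "table4_scenario",
    "validate_instance",
]
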