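"""Solver-free exact optimizer: binary search on the candidate LWT.

At a fixed candidate L, feasibility of the transfer problem decomposes
per doctor:

* a sender must shed at least ``ceil(((et+dt)*booked - min(L, wt)) / et)``
  examination services (and can shed at most ``booked``);
* a receiver can absorb at most ``floor((min(L, wt) - (et+dt)*booked) / et)``.

L is achievable iff every sender can shed what it must and the total
required sends fit into the total receiver capacity.  Required sends are
non-increasing and capacities non-decreasing in L, so feasibility is
monotone and the optimum is found by integer binary search between a
per-doctor lower bound and the point where every cap term saturates.
This is both the
default production path (no MILP solver needed) and the oracle against
which the MILP backend is verified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .instance import (
    Backend,
    ClinicInstance,
    Mode,
    SolveResult,
    Status,
    TransferPlan,
    base_workload,
    transfer_roles,
    validate_instance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeasibilityCertificate:
    """Witness for the decision 'is candidate_lwt achievable?'.

    ``required_sends`` maps each sender's roster index to its minimum
    mandatory number of shed examination services; ``receive_caps`` maps each
    receiver's index to its absorption capacity.  ``overloaded_receivers``
    lists receivers whose base workload already exceeds min(candidate, cap),
    which no transfer can fix (receivers never send).
    """

    candidate_lwt: int
    required_sends: dict[int, int]
    receive_caps: dict[int, int]
    overloaded_receivers: tuple[int, ...]
    feasible: bool


def min_required_send(instance: ClinicInstance, doctor_index: int,
                      candidate_lwt: int) -> int:
    """Least number of examination services a sender must shed so that its
    post-plan workload satisfies both its own cap and the candidate LWT."""
    d = instance.doctors[doctor_index]
    limit = min(candidate_lwt, d.work_time)
    excess = instance.service_time * d.booked - limit
    return max(0, math.ceil(excess / instance.et))


def max_receive_cap(instance: ClinicInstance, doctor_index: int,
                    candidate_lwt: int) -> int:
    """Most examination services a receiver can absorb without exceeding its
    cap or the candidate LWT."""
    d = instance.doctors[doctor_index]
    limit = min(candidate_lwt, d.work_time)
    slack = limit - instance.service_time * d.booked
    return max(0, slack // instance.et)


def feasible_at(instance: ClinicInstance, candidate_lwt: int,
                mode: Mode | str = Mode.LEAN) -> FeasibilityCertificate:
    """Decide whether some conservation-satisfying plan achieves
    ``candidate_lwt``; the certificate carries the per-doctor evidence."""
    roles = transfer_roles(instance, mode)
    sends: dict[int, int] = {}
    caps: dict[int, int] = {}
    overloaded: list[int] = []
    for i, role in enumerate(roles):
        if role == "send":
            sends[i] = min_required_send(instance, i, candidate_lwt)
        else:
            caps[i] = max_receive_cap(instance, i, candidate_lwt)
            d = instance.doctors[i]
            if instance.service_time * d.booked > min(candidate_lwt, d.work_time):
                overloaded.append(i)
    ok = (
        not overloaded
        and all(sends[i] <= instance.doctors[i].booked for i in sends)
        and sum(sends.values()) <= sum(caps.values())
    )
    return FeasibilityCertificate(
        candidate_lwt=candidate_lwt,
        required_sends=sends,
        receive_caps=caps,
        overloaded_receivers=tuple(overloaded),
        feasible=ok,
    )


def _lower_bound(instance: ClinicInstance, roles) -> int:
    """Largest over doctors of the minimum workload any plan can leave them:
    dt*booked for a sender (it keeps every diagnosis service), the full base
    workload for a receiver."""
    lb = 0
    for i, role in enumerate(roles):
        b = instance.doctors[i].booked
        lb = max(lb, instance.dt * b if role == "send"
                 else instance.service_time * b)
    return lb


def canonical_plan(instance: ClinicInstance, optimal_lwt: int,
                   mode: Mode | str = Mode.LEAN) -> TransferPlan:
    """Deterministic optimal plan at a feasible LWT.

    Every sender sheds exactly its minimum required count; the total is
    handed to receivers in roster order, each filled up to its capacity.
    The optimum is typically degenerate (many plans achieve the same LWT);
    this minimal-total-transfer, roster-ordered fill is the package's fixed
    tie-break.
    """
    cert = feasible_at(instance, optimal_lwt, mode)
    if not cert.feasible:
        raise ValueError(f"candidate LWT {optimal_lwt} is not feasible; "
                         "canonical_plan requires a feasible value")
    npp = [0] * instance.td
    for i, s in cert.required_sends.items():
        npp[i] = -s
    remaining = sum(cert.required_sends.values())
    for i, cap in cert.receive_caps.items():
        take = min(cap, remaining)
        npp[i] = take
        remaining -= take
        if remaining == 0:
            break
    assert remaining == 0, "certificate guaranteed total capacity"
    return TransferPlan(tuple(npp))


def solve_exact(instance: ClinicInstance,
                mode: Mode | str = Mode.LEAN) -> SolveResult:
    """Minimize the maximum post-plan working time (LWT) exactly.

    Binary-searches the smallest integer L with a feasible certificate,
    then attaches the canonical plan.
    Returns status ``infeasible`` when a working-time cap cannot be met even
    with maximal transfers (e.g. an overloaded doctor with no receiver).
    """
    mode = Mode(mode)
    violations = validate_instance(instance)
    if violations:
        raise ValueError("invalid instance: " + "; ".join(violations))

    roles = transfer_roles(instance, mode)
    lo = _lower_bound(instance, roles)
    # beyond max(base, cap) every min(L, work_time) term saturates, so
    # feasibility is constant above hi; note hi can exceed the max base
    # workload when a tight cap forces transfers onto a receiver
    hi = max(max(base_workload(instance, i) for i in range(instance.td)),
             max(d.work_time for d in instance.doctors))
    hi = max(hi, lo)
    if not feasible_at(instance, hi, mode).feasible:
        logger.info("infeasible: caps cannot be met at upper bound %d", hi)
        return SolveResult(lwt=None, plan=None, mode=mode,
                           backend=Backend.EXACT, status=Status.INFEASIBLE)
    while lo < hi:
        mid = (lo + hi) // 2
        cert = feasible_at(instance, mid, mode)
        logger.debug("candidate %d: feasible=%s sends=%s caps=%s", mid,
                     cert.feasible, cert.required_sends, cert.receive_caps)
        if cert.feasible:
            hi = mid
        else:
            lo = mid + 1
    plan = canonical_plan(instance, lo, mode)
    logger.info("optimal LWT %d (mode=%s, %d doctors)", lo, mode.value,
                instance.td)
    return SolveResult(lwt=lo, plan=plan, mode=mode, backend=Backend.EXACT,
                       status=Status.OPTIMAL)
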