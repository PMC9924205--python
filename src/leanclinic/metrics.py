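"""Efficiency and flow metrics, plus before/after workload reports.

RTS measures the relative reduction in senior working time at fixed
caseload::

    RTS = 1 - LWT * SD / sum_{seniors}(booked * (et + dt))

RTDS measures the relative increase in associate patient throughput::

    RTDS = LWT * ASD / sum_{associates}(booked * (et + dt)) - 1

Both are defined from the optimized LWT, not from realized per-doctor
workloads — even when some associates end below the LWT — so a published
value computed the same way is reproduced rather than 'corrected'.
SNPP/ANPP summarize the extreme transfer counts per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .instance import (
    ClinicInstance,
    Rank,
    SolveResult,
    Status,
    TransferPlan,
    base_workload,
    post_workload,
)


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    lwt: int
    rts: float
    rtds: float
    snpp: int
    anpp: int
    workloads_before: tuple[int, ...]
    workloads_after: tuple[int, ...]

    def to_dict(self) -> dict:
        """JSON payload; fractions are unrounded (tables round half-up)."""
        return {"lwt": self.lwt, "rts": self.rts, "rtds": self.rtds,
                "snpp": self.snpp, "anpp": self.anpp}


def rts(instance: ClinicInstance, lwt: int) -> float:
    """Senior work-efficiency gain: 1 - LWT*SD / (senior booked time)."""
    denom = sum(d.booked for d in instance.doctors
                if d.rank is Rank.SENIOR) * instance.service_time
    if instance.tds < 1 or denom == 0:
        raise ValueError("RTS undefined: no senior workload")
    return float(1 - Fraction(lwt * instance.tds, denom))


def rtds(instance: ClinicInstance, lwt: int) -> float:
    """Associate patient-flow gain: LWT*ASD / (associate booked time) - 1."""
    denom = sum(d.booked for d in instance.doctors
                if d.rank is Rank.ASSOCIATE) * instance.service_time
    if instance.asd < 1 or denom == 0:
        raise ValueError("RTDS undefined: no associate workload")
    return float(Fraction(lwt * instance.asd, denom) - 1)


def group_transfer_summary(plan: TransferPlan,
                           instance: ClinicInstance) -> tuple[int, int]:
    """(SNPP, ANPP): most-negative senior npp, largest associate npp."""
    if len(plan.npp) != instance.td:
        raise ValueError("plan does not align with the instance roster")
    senior = [plan.npp[i] for i, d in enumerate(instance.doctors)
              if d.rank is Rank.SENIOR]
    assoc = [plan.npp[i] for i, d in enumerate(instance.doctors)
             if d.rank is Rank.ASSOCIATE]
    return (min(senior) if senior else 0, max(assoc) if assoc else 0)


def before_after_table(instance: ClinicInstance,
                       result: SolveResult) -> pd.DataFrame:
    """Per-doctor workload comparison; last row totals the columns.

    Columns: doctor_id, rank, booked, npp, workload_before, workload_after.
    For any conservation-satisfying plan the two workload totals agree.
    """
    if result.status is not Status.OPTIMAL or result.plan is None:
        raise ValueError("before/after table requires an optimal result")
    rows = []
    for i, d in enumerate(instance.doctors):
        rows.append({
            "doctor_id": d.id,
            "rank": d.rank.value,
            "booked": d.booked,
            "npp": result.plan.npp[i],
            "workload_before": base_workload(instance, i),
            "workload_after": post_workload(instance, result.plan, i),
        })
    df = pd.DataFrame(rows)
    totals = {
        "doctor_id": "TOTAL", "rank": "", "booked": df["booked"].sum(),
        "npp": df["npp"].sum(),
        "workload_before": df["workload_before"].sum(),
        "workload_after": df["workload_after"].sum(),
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def compute_metrics(instance: ClinicInstance,
                    result: SolveResult) -> MetricsReport:
    if result.status is not Status.OPTIMAL or result.plan is None:
        raise ValueError("metrics require an optimal result")
    snpp, anpp = group_transfer_summary(result.plan, instance)
    return MetricsReport(
        lwt=result.lwt,
        rts=rts(instance, result.lwt),
        rtds=rtds(instance, result.lwt),
        snpp=snpp,
        anpp=anpp,
        workloads_before=tuple(base_workload(instance, i)
                               for i in range(instance.td)),
        workloads_after=tuple(post_workload(instance, result.plan, i)
                              for i in range(instance.td)),
    )
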