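"""Clinic instance data model, validation, serialization and workload arithmetic.

A :class:`ClinicInstance` holds the doctor roster (seniors listed before
associates), the per-patient examination time ``et`` and diagnosis time
``dt``, and optionally a binary doctor-by-patient appointment matrix whose
row sums equal each doctor's booked count.  A :class:`TransferPlan` assigns
each doctor a signed integer ``npp``: the number of examination services
transferred in (positive) or out (negative).

Workloads are purely arithmetic: a doctor's base working time is
``(et + dt) * booked`` and a plan shifts it by ``et * npp`` (only the
examination stage moves between doctors; the diagnosis stage stays with the
booked doctor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence


class Rank(str, Enum):
    SENIOR = "senior"
    ASSOCIATE = "associate"


class Mode(str, Enum):
    """Sign-constraint regime for transfers.

    ``lean``: seniors may only shed examination services (npp <= 0) and
    associates may only absorb them (npp >= 0) — the refined clinical
    pathway.  ``as_printed``: a doctor's allowed sign depends on whether its
    booked count exceeds the global average ``tp / td``, regardless of rank.
    """

    LEAN = "lean"
    AS_PRINTED = "as_printed"


class Backend(str, Enum):
    EXACT = "exact"
    MILP = "milp"


class Status(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"


def _is_int(x) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


@dataclass(frozen=True)
class DoctorRecord:
    """One doctor: label, rank, booked-patient count and working-time cap."""

    id: str
    rank: Rank
    booked: int
    work_time: int


@dataclass(frozen=True)
class ClinicInstance:
    doctors: tuple[DoctorRecord, ...]
    et: int
    dt: int
    appointment_matrix: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "doctors", tuple(self.doctors))
        if self.appointment_matrix is not None:
            object.__setattr__(
                self, "appointment_matrix",
                tuple(tuple(row) for row in self.appointment_matrix))

    # -- derived counts ---------------------------------------------------
    @property
    def td(self) -> int:
        """Total number of doctors."""
        return len(self.doctors)

    @property
    def tds(self) -> int:
        """Number of senior doctors."""
        return sum(1 for d in self.doctors if d.rank is Rank.SENIOR)

    @property
    def asd(self) -> int:
        """Number of associate senior doctors."""
        return self.td - self.tds

    @property
    def tp(self) -> int:
        """Total booked patients."""
        return sum(d.booked for d in self.doctors)

    @property
    def service_time(self) -> int:
        """Full per-patient service duration, et + dt."""
        return self.et + self.dt

    @property
    def booked(self) -> tuple[int, ...]:
        return tuple(d.booked for d in self.doctors)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "et": self.et,
            "dt": self.dt,
            "doctors": [
                {"id": d.id, "rank": d.rank.value, "booked": d.booked,
                 "work_time": d.work_time}
                for d in self.doctors
            ],
        }
        if self.appointment_matrix is not None:
            out["dpat"] = [list(row) for row in self.appointment_matrix]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "ClinicInstance":
        doctors = tuple(
            DoctorRecord(id=str(d["id"]), rank=Rank(d["rank"]),
                         booked=d["booked"], work_time=d["work_time"])
            for d in data["doctors"]
        )
        matrix = data.get("dpat")
        return cls(doctors=doctors, et=data["et"], dt=data["dt"],
                   appointment_matrix=matrix)

    @classmethod
    def from_json(cls, source: str | Path) -> "ClinicInstance":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class TransferPlan:
    """Signed examination-service transfer counts, aligned with the roster."""

    npp: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "npp", tuple(self.npp))

    @classmethod
    def zeros(cls, n: int) -> "TransferPlan":
        return cls(npp=(0,) * n)


@dataclass(frozen=True)
class SolveResult:
    lwt: int | None
    plan: TransferPlan | None
    mode: Mode
    backend: Backend
    status: Status

    def to_dict(self) -> dict:
        return {
            "lwt": self.lwt,
            "mode": self.mode.value,
            "backend": self.backend.value,
            "status": self.status.value,
            "npp": list(self.plan.npp) if self.plan is not None else None,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "SolveResult":
        npp = data.get("npp")
        return cls(lwt=data["lwt"],
                   plan=TransferPlan(tuple(npp)) if npp is not None else None,
                   mode=Mode(data["mode"]), backend=Backend(data["backend"]),
                   status=Status(data["status"]))


# ---------------------------------------------------------------------------
# roles

def transfer_roles(instance: ClinicInstance, mode: Mode | str) -> tuple[str, ...]:
    """Per-doctor transfer direction, ``"send"`` (npp <= 0) or ``"receive"``
    (npp >= 0), under the given mode.

    In lean mode the role follows rank.  In as_printed mode it follows the
    comparison of the doctor's booked count with the global average tp/td,
    evaluated as an exact rational; a doctor exactly at the average may
    receive.
    """
    mode = Mode(mode)
    if mode is Mode.LEAN:
        return tuple("send" if d.rank is Rank.SENIOR else "receive"
                     for d in instance.doctors)
    avg = Fraction(instance.tp, instance.td)
    return tuple("send" if d.booked > avg else "receive"
                 for d in instance.doctors)


# ---------------------------------------------------------------------------
# validation

def validate_instance(instance: ClinicInstance) -> list[str]:
    """Check every instance invariant; return human-readable violations.

    Returns an empty list iff the instance is valid.  Never raises.
    """
    v: list[str] = []
    for name, val in (("et", instance.et), ("dt", instance.dt)):
        if not _is_int(val):
            v.append(f"{name} must be an integer, got {val!r}")
        elif val <= 0:
            v.append(f"{name} must be > 0, got {val}")
    seen_associate = False
    for i, d in enumerate(instance.doctors):
        if not isinstance(d.rank, Rank):
            v.append(f"doctor {i} ({d.id}): invalid rank {d.rank!r}")
            continue
        if d.rank is Rank.ASSOCIATE:
            seen_associate = True
        elif seen_associate:
            v.append(f"doctor {i} ({d.id}): senior listed after an associate "
                     "(roster must list all seniors first)")
        if not _is_int(d.booked) or d.booked < 0:
            v.append(f"doctor {i} ({d.id}): booked must be an integer >= 0, "
                     f"got {d.booked!r}")
        if not _is_int(d.work_time) or d.work_time < 0:
            v.append(f"doctor {i} ({d.id}): work_time must be an integer >= 0, "
                     f"got {d.work_time!r}")
    if instance.tds == 0:
        v.append("instance has no senior doctor")
    if instance.asd == 0:
        v.append("instance has no associate senior doctor")

    m = instance.appointment_matrix
    if m is not None:
        if len(m) != instance.td:
            v.append(f"appointment matrix has {len(m)} rows for "
                     f"{instance.td} doctors")
        else:
            widths = {len(row) for row in m}
            if len(widths) > 1:
                v.append("appointment matrix rows have unequal lengths")
            else:
                for i, row in enumerate(m):
                    if any(x not in (0, 1) for x in row):
                        v.append(f"doctor {i}: matrix row has non-binary entries")
                    elif sum(row) != instance.doctors[i].booked:
                        v.append(f"doctor {i} ({instance.doctors[i].id}): matrix "
                                 f"row sums to {sum(row)}, booked is "
                                 f"{instance.doctors[i].booked}")
                ncols = len(m[0]) if m else 0
                for j in range(ncols):
                    s = sum(row[j] for row in m)
                    if s != 1:
                        v.append(f"patient {j}: appointed to {s} doctors "
                                 "(must be exactly 1)")
    return v


# ---------------------------------------------------------------------------
# workload arithmetic

def base_workload(instance: ClinicInstance, doctor_index: int) -> int:
    """Pre-plan working time of one doctor: (et + dt) * booked."""
    if not 0 <= doctor_index < instance.td:
        raise IndexError(f"doctor index {doctor_index} out of range "
                         f"[0, {instance.td})")
    return instance.service_time * instance.doctors[doctor_index].booked


def post_workload(instance: ClinicInstance, plan: TransferPlan,
                  doctor_index: int) -> int:
    """Post-plan working time: base workload plus et per transferred-in exam.

    May exceed the doctor's cap or any LWT; constraint checking is
    :func:`check_plan`'s job.
    """
    if len(plan.npp) != instance.td:
        raise ValueError(f"plan length {len(plan.npp)} does not match roster "
                         f"size {instance.td}")
    return base_workload(instance, doctor_index) + instance.et * plan.npp[doctor_index]


def check_plan(instance: ClinicInstance, plan: TransferPlan,
               mode: Mode | str, lwt: int) -> list[str]:
    """Verify a plan against the caps, the LWT bound, the mode's sign
    constraints, conservation and the per-doctor send bound.

    Returns an empty list iff the plan is feasible at ``lwt``.
    """
    if len(plan.npp) != instance.td:
        raise ValueError(f"plan length {len(plan.npp)} does not match roster "
                         f"size {instance.td}")
    roles = transfer_roles(instance, mode)
    v: list[str] = []
    for i, d in enumerate(instance.doctors):
        w = post_workload(instance, plan, i)
        if w > d.work_time:
            v.append(f"doctor {i} ({d.id}): post-plan workload {w} exceeds "
                     f"cap {d.work_time}")
        if w > lwt:
            v.append(f"doctor {i} ({d.id}): post-plan workload {w} exceeds "
                     f"LWT {lwt}")
        if roles[i] == "send" and plan.npp[i] > 0:
            v.append(f"doctor {i} ({d.id}): sender has positive npp "
                     f"{plan.npp[i]}")
        if roles[i] == "receive" and plan.npp[i] < 0:
            v.append(f"doctor {i} ({d.id}): receiver has negative npp "
                     f"{plan.npp[i]}")
        if plan.npp[i] < -d.booked:
            v.append(f"doctor {i} ({d.id}): transfers out {-plan.npp[i]} "
                     f"but only {d.booked} booked")
    total = sum(plan.npp)
    if total != 0:
        v.append(f"transfers do not conserve patients: sum(npp) = {total}")
    return v
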