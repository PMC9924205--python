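"""Instance generators: the published experimental designs plus seeded
random instances for property testing.

Two families reproduce the source study's inputs:

* :func:`table2_row` — the factorial sweep around a 20-doctor clinic
  (10 seniors booked 36, 10 associates booked 18, caps 360) varying the
  examination/diagnosis split ``et + dt = 10``; optional ``sd``/``asd``
  knobs expose the staffing sweep with the same per-doctor bookings.
* :func:`table4_scenario` — six named before/after scenarios at
  ``et = dt = 5`` with structured booking patterns.

:func:`random_instance` draws reproducible instances from explicit ranges;
identical seed and ranges give byte-identical JSON.
"""

from __future__ import annotations

import numpy as np

from .instance import ClinicInstance, DoctorRecord, Rank

_WT = 360
_SENIOR_BOOKED = 36
_ASSOC_BOOKED = 18

_SCENARIO_BOOKINGS: dict[int, tuple[list[int], list[int]]] = {
    1: ([36] * 10, [18] * 10),
    2: ([36, 18] * 5, [18] * 10),
    3: ([36, 30, 36, 28, 36, 26, 36, 24, 36, 22], [18] * 10),
    4: ([36, 30, 36, 28, 36, 26, 36, 24, 36, 22], [18, 24] * 5),
    5: ([36] * 10, [18, 24] * 5),
    6: ([36, 30, 36, 28, 36, 26, 36, 24, 36, 22],
        [18, 30, 18, 28, 18, 26, 18, 24, 18, 22]),
}


def _roster(senior_booked, associate_booked, work_time: int) -> tuple[DoctorRecord, ...]:
    doctors = [DoctorRecord(id=f"S{i + 1}", rank=Rank.SENIOR, booked=int(b),
                            work_time=work_time)
               for i, b in enumerate(senior_booked)]
    doctors += [DoctorRecord(id=f"A{i + 1}", rank=Rank.ASSOCIATE, booked=int(b),
                             work_time=work_time)
                for i, b in enumerate(associate_booked)]
    return tuple(doctors)


def table2_row(et: int, dt: int, sd: int = 10, asd: int = 10) -> ClinicInstance:
    """Factorial-sweep instance: ``sd`` seniors booked 36, ``asd`` associates
    booked 18, caps 360, with the given examination/diagnosis split.

    The design fixes ``et + dt = 10`` with ``et`` between 2 and 8.  The
    staffing counts default to the 10+10 clinic; other values generate the
    staffing sweep (same per-doctor bookings, different head counts).
    """
    if et + dt != 10 or not 2 <= et <= 8:
        raise ValueError(f"(et, dt) = ({et}, {dt}) outside the factorial "
                         "design: need et + dt = 10 with et in 2..8")
    if sd < 1 or asd < 1:
        raise ValueError("need at least one doctor of each rank")
    return ClinicInstance(
        doctors=_roster([_SENIOR_BOOKED] * sd, [_ASSOC_BOOKED] * asd, _WT),
        et=et, dt=dt)


def table4_scenario(n: int) -> ClinicInstance:
    """One of the six named before/after scenarios (10+10 doctors,
    et = dt = 5, caps 360) with scenario-specific booking vectors."""
    if n not in _SCENARIO_BOOKINGS:
        raise ValueError(f"scenario {n} out of range 1..6")
    senior, assoc = _SCENARIO_BOOKINGS[n]
    return ClinicInstance(doctors=_roster(senior, assoc, _WT), et=5, dt=5)


def _check_range(name: str, rng: tuple[int, int], lo_min: int) -> None:
    lo, hi = rng
    if lo > hi or lo < lo_min:
        raise ValueError(f"degenerate {name} range {rng}: need "
                         f"{lo_min} <= lo <= hi")


def random_instance(seed: int,
                    td_range: tuple[int, int] = (2, 8),
                    booked_range: tuple[int, int] = (0, 40),
                    et_range: tuple[int, int] = (1, 8),
                    dt_range: tuple[int, int] = (1, 8),
                    work_time_range: tuple[int, int] | None = None,
                    ) -> ClinicInstance:
    """Seeded random instance with at least one doctor of each rank.

    When ``work_time_range`` is omitted, every cap is set to twice the
    largest base workload, so caps never bind and any sign-constraint mode
    is feasible; pass an explicit range to exercise tight or infeasible
    caps.
    """
    _check_range("td", td_range, 2)
    _check_range("booked", booked_range, 0)
    _check_range("et", et_range, 1)
    _check_range("dt", dt_range, 1)
    if work_time_range is not None:
        _check_range("work_time", work_time_range, 0)

    rng = np.random.default_rng(seed)
    td = int(rng.integers(td_range[0], td_range[1] + 1))
    tds = int(rng.integers(1, td))
    et = int(rng.integers(et_range[0], et_range[1] + 1))
    dt = int(rng.integers(dt_range[0], dt_range[1] + 1))
    booked = [int(b) for b in rng.integers(booked_range[0],
                                           booked_range[1] + 1, size=td)]
    if work_time_range is not None:
        wts = [int(w) for w in rng.integers(work_time_range[0],
                                            work_time_range[1] + 1, size=td)]
    else:
        ample = 2 * (et + dt) * max(max(booked), 1)
        wts = [ample] * td
    doctors = tuple(
        DoctorRecord(id=f"{'S' if i < tds else 'A'}{i + 1}",
                     rank=Rank.SENIOR if i < tds else Rank.ASSOCIATE,
                     booked=booked[i], work_time=wts[i])
        for i in range(td))
    return ClinicInstance(doctors=doctors, et=et, dt=dt)


def expand_matrix(instance: ClinicInstance) -> ClinicInstance:
    """Attach the binary doctor-by-patient appointment matrix implied by the
    booked counts (patients numbered doctor by doctor, booking by booking).

    Idempotent on instances already carrying a consistent matrix; an
    inconsistent existing matrix raises.
    """
    if instance.appointment_matrix is not None:
        m = instance.appointment_matrix
        ok = (len(m) == instance.td
              and all(sum(row) == d.booked
                      for row, d in zip(m, instance.doctors))
              and all(sum(row[j] for row in m) == 1
                      for j in range(len(m[0]) if m else 0)))
        if not ok:
            raise ValueError("existing appointment matrix is inconsistent "
                             "with the booked counts")
        return instance
    tp = instance.tp
    matrix = []
    start = 0
    for d in instance.doctors:
        row = [0] * tp
        for j in range(start, start + d.booked):
            row[j] = 1
        start += d.booked
        matrix.append(tuple(row))
    return ClinicInstance(doctors=instance.doctors, et=instance.et,
                          dt=instance.dt, appointment_matrix=tuple(matrix))
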