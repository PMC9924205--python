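import itertools

import pytest

from leanclinic import ClinicInstance, DoctorRecord, Rank, table4_scenario
from leanclinic.instance import transfer_roles


@pytest.fixture
def scenario1() -> ClinicInstance:
    return table4_scenario(1)


def make_instance(senior_booked, associate_booked, et, dt, work_time=360):
    """Compact roster builder for hand-crafted test instances."""
    doctors = [DoctorRecord(f"S{i}", Rank.SENIOR, b, work_time if isinstance(work_time, int) else work_time[i])
               for i, b in enumerate(senior_booked)]
    n = len(doctors)
    doctors += [DoctorRecord(f"A{i}", Rank.ASSOCIATE, b, work_time if isinstance(work_time, int) else work_time[n + i])
                for i, b in enumerate(associate_booked)]
    return ClinicInstance(doctors=tuple(doctors), et=et, dt=dt)


def brute_force_lwt(instance: ClinicInstance, mode="lean"):
    """Exhaustive enumeration oracle over all integer transfer vectors.

    Enumerates every sign- and bound-respecting npp vector, filters by
    conservation and the working-time caps, and returns the minimum over
    feasible vectors of the maximum post-plan workload (None if no vector
    is feasible).  Only viable for tiny rosters.
    """
    roles = transfer_roles(instance, mode)
    total_sendable = sum(d.booked for d, r in zip(instance.doctors, roles)
                         if r == "send")
    ranges = [range(-d.booked, 1) if r == "send"
              else range(0, total_sendable + 1)
              for d, r in zip(instance.doctors, roles)]
    best = None
    st, et = instance.service_time, instance.et
    for npp in itertools.product(*ranges):
        if sum(npp) != 0:
            continue
        workloads = [st * d.booked + et * n
                     for d, n in zip(instance.doctors, npp)]
        if any(w > d.work_time for w, d in zip(workloads, instance.doctors)):
            continue
        m = max(workloads)
        if best is None or m < best:
            best = m
    return best
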