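"""Exact binary-search optimizer: formulas, certificates, optimality."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leanclinic import (
    ClinicInstance,
    DoctorRecord,
    Rank,
    Status,
    canonical_plan,
    check_plan,
    feasible_at,
    solve_exact,
    table2_row,
)
from leanclinic.exact import max_receive_cap, min_required_send
from leanclinic.generate import random_instance
from leanclinic.instance import base_workload, transfer_roles

from conftest import brute_force_lwt, make_instance


class TestSendAndReceiveFormulas:
    @pytest.mark.parametrize("booked,et,dt,candidate,expected", [
        (36, 8, 2, 272, 11),   # busiest sender of the et/dt sweep
        (36, 5, 5, 360, 0),    # base workload already within the candidate
        (30, 5, 5, 265, 7),    # mid-booked sender of the mixed scenario
    ])
    def test_min_required_send(self, booked, et, dt, candidate, expected):
        inst = make_instance([booked], [1], et=et, dt=dt)
        assert min_required_send(inst, 0, candidate) == expected

    def test_min_required_send_clamped_by_cap(self):
        # cap 300 binds even though the candidate allows 330
        inst = make_instance([36], [1], et=5, dt=5, work_time=300)
        assert min_required_send(inst, 0, 330) == 12

    @pytest.mark.parametrize("booked,et,dt,candidate,expected", [
        (18, 8, 2, 272, 11),
        (18, 5, 5, 180, 0),
        (24, 5, 5, 285, 9),
    ])
    def test_max_receive_cap(self, booked, et, dt, candidate, expected):
        inst = make_instance([1], [booked], et=et, dt=dt)
        assert max_receive_cap(inst, 1, candidate) == expected


class TestFeasibility:
    def test_sweep_row_feasible_at_optimum(self):
        inst = table2_row(et=8, dt=2)
        cert = feasible_at(inst, 272)
        assert cert.feasible
        assert sum(cert.required_sends.values()) == 110
        assert sum(cert.receive_caps.values()) == 110

    def test_sweep_row_infeasible_one_below(self):
        cert = feasible_at(table2_row(et=8, dt=2), 271)
        assert not cert.feasible
        assert sum(cert.required_sends.values()) == 120
        assert sum(cert.receive_caps.values()) == 110

    def test_max_base_workload_always_feasible(self, scenario1):
        ub = max(base_workload(scenario1, i) for i in range(scenario1.td))
        cert = feasible_at(scenario1, ub)
        assert cert.feasible
        assert all(s == 0 for s in cert.required_sends.values())

    @given(st.integers(0, 2**31 - 1), st.integers(0, 400))
    @settings(derandomize=True, max_examples=150)
    def test_feasibility_monotone_in_candidate(self, seed, candidate):
        inst = random_instance(seed, td_range=(2, 6), booked_range=(0, 12),
                               work_time_range=(0, 150))
        if feasible_at(inst, candidate).feasible:
            assert feasible_at(inst, candidate + 1).feasible


class TestSolveExact:
    def test_balanced_split_sweep_row(self):
        assert solve_exact(table2_row(et=5, dt=5)).lwt == 270

    def test_short_exam_row_senders_capped_at_booked(self):
        res = solve_exact(table2_row(et=2, dt=8))
        assert res.lwt == 288
        assert res.plan.npp[:10] == (-36,) * 10

    def test_two_doctor_instance_matches_hand_enumeration(self):
        # npp in {0,-1,-2}: workloads (4,2), (3,3), (2,4) -> optimum 3
        inst = make_instance([2], [1], et=1, dt=1, work_time=100)
        res = solve_exact(inst)
        assert res.lwt == 3
        assert res.plan.npp == (-1, 1)

    def test_infeasible_when_receiver_cap_unreachable(self):
        # associate's base workload 10 exceeds its own cap 5 and
        # associates cannot shed work in lean mode
        inst = make_instance([4], [5], et=1, dt=1, work_time=[100, 5])
        res = solve_exact(inst)
        assert res.status is Status.INFEASIBLE
        assert res.lwt is None and res.plan is None

    def test_infeasible_when_sender_cap_unreachable(self):
        # even shedding every exam leaves the senior at dt*booked = 50 > 40
        inst = make_instance([10], [0], et=1, dt=5, work_time=[40, 1000])
        assert solve_exact(inst).status is Status.INFEASIBLE

    def test_invalid_instance_raises(self):
        inst = make_instance([-1], [1], et=1, dt=1)
        with pytest.raises(ValueError, match="invalid instance"):
            solve_exact(inst)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_matches_brute_force_on_tiny_instances(self, seed):
        inst = random_instance(seed, td_range=(2, 4), booked_range=(0, 5),
                               et_range=(1, 4), dt_range=(1, 4),
                               work_time_range=(0, 40))
        res = solve_exact(inst)
        oracle = brute_force_lwt(inst)
        if oracle is None:
            assert res.status is Status.INFEASIBLE
        else:
            assert res.status is Status.OPTIMAL and res.lwt == oracle

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_lower_bound_soundness(self, seed):
        inst = random_instance(seed, td_range=(2, 6), booked_range=(0, 15))
        res = solve_exact(inst)
        roles = transfer_roles(inst, "lean")
        for i, role in enumerate(roles):
            b = inst.doctors[i].booked
            floor = inst.dt * b if role == "send" else inst.service_time * b
            assert res.lwt >= floor

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_idle_associate_never_hurts(self, seed):
        inst = random_instance(seed, td_range=(2, 5), booked_range=(0, 10))
        extra = inst.doctors + (DoctorRecord("A_idle", Rank.ASSOCIATE, 0,
                                             inst.doctors[0].work_time),)
        bigger = ClinicInstance(extra, et=inst.et, dt=inst.dt)
        assert solve_exact(bigger).lwt <= solve_exact(inst).lwt

    @given(st.integers(0, 2**31 - 1), st.integers(0, 5))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_tightening_a_cap_never_helps(self, seed, which):
        inst = random_instance(seed, td_range=(2, 5), booked_range=(0, 10))
        res = solve_exact(inst)
        i = which % inst.td
        d = inst.doctors[i]
        tighter = list(inst.doctors)
        tighter[i] = DoctorRecord(d.id, d.rank, d.booked, d.work_time // 2)
        res2 = solve_exact(ClinicInstance(tuple(tighter), inst.et, inst.dt))
        if res2.status is Status.OPTIMAL:
            assert res2.lwt >= res.lwt


class TestCanonicalPlan:
    def test_sweep_row_plan_structure(self):
        inst = table2_row(et=8, dt=2)
        plan = canonical_plan(inst, 272)
        assert plan.npp[:10] == (-11,) * 10
        assert sum(plan.npp[10:]) == 110
        assert all(0 <= n <= 11 for n in plan.npp[10:])
        assert check_plan(inst, plan, "lean", 272) == []

    def test_no_sender_over_candidate_gives_zero_plan(self, scenario1):
        assert canonical_plan(scenario1, 360).npp == (0,) * 20

    def test_roster_order_greedy_fill(self):
        # required sends (3, 5), receiver caps (6, 6) -> receivers (+6, +2)
        inst = make_instance([5, 6], [1, 1], et=1, dt=1,
                             work_time=[7, 7, 8, 8])
        cert = feasible_at(inst, 8)
        assert cert.required_sends == {0: 3, 1: 5}
        assert cert.receive_caps == {2: 6, 3: 6}
        assert canonical_plan(inst, 8).npp == (-3, -5, 6, 2)

    def test_infeasible_candidate_raises(self):
        inst = table2_row(et=8, dt=2)
        with pytest.raises(ValueError, match="not feasible"):
            canonical_plan(inst, 271)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_optimal_plan_always_passes_check(self, seed):
        inst = random_instance(seed, td_range=(2, 6), booked_range=(0, 12))
        res = solve_exact(inst)
        assert check_plan(inst, res.plan, "lean", res.lwt) == []
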