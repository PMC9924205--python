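# Methods

## Problem and model

A clinic day is described by a roster of `td` doctors — `tds` seniors
followed by `td − tds` associate seniors — each with an integer booked
patient count `b_i` and an integer working-time cap `wt_i` (time units; 360
in the reference experiments, i.e. a 6-hour session in minutes). Every
visit consists of an examination service of duration `et` and a diagnosis
service of duration `dt`, both integers. Only examination services move:
doctor `i`'s post-plan working time is `(et + dt)·b_i + et·npp_i`, where the
decision variable `npp_i` is the signed integer number of examination
services transferred in. The objective is the minimal achievable value of
the maximum post-plan working time, `LWT`, subject to per-doctor caps,
conservation `Σ npp_i = 0`, the send bound `npp_i ≥ −b_i`, and a
sign-constraint mode (below).

The model assumes: deterministic, patient-independent service durations;
transfers measured in counts, not identities (the optional binary
doctor×patient matrix only documents bookings: each column sums to 1, row
sums equal `b_i`); no queueing, arrival-time, or no-show behavior.

`npp` and `LWT` are treated as integers even though the source formulation
labels them continuous: every published solution is integer-valued, and for
integer inputs the optimum provably is too (the minimized LWT equals a
maximum of integer workloads). The package therefore requires integer
inputs and reports integer results.

## Sign-constraint modes

* **lean** (default): seniors may only shed (`npp_i ≤ 0`), associates may
  only absorb (`npp_i ≥ 0`). This mirrors the refined clinical pathway and
  reproduces all twelve verifiable published optima.
* **as_printed**: the direction is set by each doctor's booked count versus
  the clinic average `tp/td`, compared as an exact rational with ties
  allowed to receive — a doctor above average may only shed, at or below
  average only absorb, regardless of rank. This is the literal reading of
  the source's per-rank sign constraints (whose printed index ranges are
  garbled; the per-doctor-booked reading is the only meaningful one, since
  a per-patient column of the appointment matrix always sums to 1). It is a
  different polytope, not a relaxation of lean, and yields strictly smaller
  optima on some published scenarios (225 vs. the printed 240 on the
  alternating-seniors scenario), so it is provided for fidelity and
  excluded from reproduction claims. Empirically — and in the seeded
  property suite — its optimum never exceeds lean's when caps do not bind:
  the average rule always frees at least the load-shedding directions lean
  uses.

## Exact solver

At a fixed candidate `L`, write `lim_i = min(L, wt_i)`. A sender must shed
at least `s_i = max(0, ceil(((et+dt)·b_i − lim_i) / et))` services and can
shed at most `b_i`; a receiver can absorb at most
`r_i = max(0, floor((lim_i − (et+dt)·b_i) / et))`. Candidate `L` is
achievable iff no receiver's base workload exceeds `lim_i` (receivers
cannot shed), every `s_i ≤ b_i`, and `Σ s_i ≤ Σ r_i`. All three conditions
are monotone in `L`, so the optimum is the smallest feasible integer,
found by binary search.

Search interval: the lower end is the largest per-doctor workload floor —
`dt·b_i` for a sender (it keeps all diagnosis services), `(et+dt)·b_i` for
a receiver. The upper end is `max(max_i (et+dt)·b_i, max_i wt_i)`: beyond
it every `min(L, wt_i)` term saturates and feasibility is constant, so
infeasibility there is global (status `infeasible`, e.g. an overloaded
associate that nothing may shed for). The upper end deliberately exceeds
the largest base workload because a tight cap can *force* transfers that
push a receiver above it — a case the brute-force oracle exposed during
development.

The optimum is typically degenerate. The **canonical plan** is the
package's fixed tie-break: each sender sheds exactly `s_i` (minimal total
transfers — senders already under the candidate send nothing), and the
total is given to receivers in roster order, each filled to `r_i`. Only
the optimal LWT, never a specific transfer vector, is certified against
published results, which report a solver-arbitrary optimum (one published
scenario sends 34 from a senior where 22 suffices).

## MILP backend

`build_model` emits the ILP symbolically (one continuous `LWT ≥ 0`, `td`
integer `npp` variables; `td` cap rows, `td` LWT rows, one conservation
equality; sign constraints as variable bounds, with receiver upper bounds
left implied by the cap/LWT rows) plus an LP-format export for inspection.
`solve_milp` dispatches by solver name; HiGHS through `scipy.optimize.milp`
is the registered backend, and unknown names raise an environment error
with an install hint. Returned `npp` values are accepted as integral within
1e-6 and the LWT is re-derived from the integral plan as the max post-plan
workload, eliminating float residue; a disagreement beyond 1e-6 with the
solver's objective raises. The exact solver is the oracle: the seeded
suite requires LWT agreement on random instances in both modes, including
propagated infeasibility.

## Metrics

`RTS = 1 − LWT·SD / (Σ_seniors b_i·(et+dt))` and
`RTDS = LWT·ASD / (Σ_associates b_i·(et+dt)) − 1` are computed from the
*optimized LWT*, exactly as published — even when some associates end
below the LWT, RTDS is not recomputed from realized workloads. Both are
undefined (error) when the respective group has no booked time. Tables
round half-up to 2 decimals; JSON output keeps unrounded values (one
published minimum appears as both 16% and 0.17 — truncated vs. rounded —
and the unrounded 1/6 reproduces either).

## Generators and what they do and don't emulate

`table2_row(et, dt, sd=10, asd=10)` builds the factorial-sweep clinic:
per-doctor bookings fixed at 36 (senior) and 18 (associate), caps 360,
`et + dt = 10` with `et ∈ {2..8}`. The published sweep's stated total of
540 patients is inconsistent with fixed per-doctor bookings once staffing
varies; the generator keeps the 36/18 bookings (the reading consistent
with the published RTS/RTDS values) and derives the total from the roster.
`table4_scenario(1..6)` builds the six before/after scenarios
(`et = dt = 5`, caps 360, 10+10 doctors, scenario-specific booking
vectors). `random_instance(seed, ...)` draws reproducible rosters from
explicit ranges, with ample (non-binding) caps unless a cap range is
given; it exists for property testing and emulates nothing clinical —
passing tests on it demonstrates solver correctness over the constraint
classes, not realism of any booking distribution.

Patients in the expanded appointment matrix are numbered doctor by doctor
in roster order — an arbitrary but fixed convention for reproducibility.

## Reproduction scope

Twelve published optima are verifiable and reproduced exactly: the seven
`et/dt` sweep rows (LWT 272, 271, 270, 270, 272, 270, 288) and scenarios
1–5 (270, 240, 250, 265, 285). The eight staffing-sweep rows and scenario
6 print solutions that violate their own constraints (scenario 6 prints
LWT 280 while an associate's pre-plan workload is already 300 and
associates cannot shed); `reproduce` solves them under this package's
reading and flags them `excluded: inconsistent in source`. The headline
"25% / 50% average" gains depend on the excluded rows; over the seven
verifiable rows the computed means are ≈ 0.24 and ≈ 0.52.

## Numerical choices and problem sizes

All core arithmetic is exact integer or `fractions.Fraction`; floats enter
only at the HiGHS interface (1e-6 integrality/consistency tolerance) and in
reported rates. The test suite's stochastic checks use fixed seed streams:
500 tiny instances (≤ 4 doctors, bookings ≤ 5) against exhaustive
enumeration, 200 instances per mode for exact-vs-MILP agreement, 150 for
feasibility monotonicity, 200 for the mode-comparison property — sizes at
which the full suite runs in seconds while covering every constraint
class (tight, slack and infeasible caps; empty senders; zero bookings).

## Limitations

Deterministic service times and a single daily time budget per doctor; no
waiting-time or queueing model (the lean pathway's waiting-time benefit is
motivational, not computed); transfers are anonymous counts, so no
patient-level preferences or continuity constraints; single objective —
transfer volume is minimized only as the canonical plan's tie-break, not
optimized.
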