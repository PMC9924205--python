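"""Published reference results used by the ``reproduce`` command.

Two result tables from the source study are transcribed here so the
package can solve the same inputs and report agreement row by row.

Rows 8-14 of the factorial sweep (the staffing sweep) and scenario 6 of
the before/after table are flagged ``included=False``: their printed
solutions violate the stated constraints themselves (scenario 6, for
example, prints a maximum working time of 280 while one associate's
pre-plan workload is already 300 and associates cannot shed work), so no
solver respecting those constraints can match them.  The reproduce
command still solves them under this package's reading and marks them
excluded rather than silently matching or failing.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SweepRow:
    """One row of the factorial sweep: parameters and printed results."""

    et: int
    dt: int
    sd: int
    asd: int
    lwt: int
    snpp: int
    anpp: int
    rts: float
    rtds: float
    included: bool


# rows 1-7: et/dt split sweep on the 10+10 clinic (verifiable);
# rows 8-14: staffing sweep (excluded: inconsistent in source)
TABLE2_ROWS: tuple[SweepRow, ...] = (
    SweepRow(8, 2, 10, 10, 272, -11, 11, 0.24, 0.51, True),
    SweepRow(7, 3, 10, 10, 271, -13, 13, 0.25, 0.51, True),
    SweepRow(6, 4, 10, 10, 270, -15, 15, 0.25, 0.50, True),
    SweepRow(5, 5, 10, 10, 270, -18, 18, 0.25, 0.50, True),
    SweepRow(4, 6, 10, 10, 272, -22, 22, 0.24, 0.51, True),
    SweepRow(3, 7, 10, 10, 270, -30, 30, 0.25, 0.50, True),
    SweepRow(2, 8, 10, 10, 288, -36, 36, 0.20, 0.60, True),
    SweepRow(5, 5, 2, 18, 210, -30, 6, 0.42, 0.17, False),
    SweepRow(5, 5, 4, 16, 235, -26, 10, 0.35, 0.31, False),
    SweepRow(5, 5, 6, 14, 250, -22, 14, 0.31, 0.39, False),
    SweepRow(5, 5, 8, 12, 260, -20, 16, 0.28, 0.44, False),
    SweepRow(5, 5, 12, 8, 280, -16, 20, 0.22, 0.56, False),
    SweepRow(5, 5, 14, 6, 295, -13, 23, 0.18, 0.64, False),
    SweepRow(5, 5, 16, 4, 310, -10, 26, 0.14, 0.72, False),
    SweepRow(5, 5, 18, 2, 330, -6, 30, 0.08, 0.83, False),
)

# scenario number -> (printed optimal LWT, included)
TABLE4_LWT: dict[int, tuple[int, bool]] = {
    1: (270, True),
    2: (240, True),
    3: (250, True),
    4: (265, True),
    5: (285, True),
    6: (280, False),
}

EXCLUDED_NOTE = "excluded: inconsistent in source"
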