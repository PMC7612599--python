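"""Printed worked escalation paths of the motivating detoxification trial.

Two published example trajectories of the design are used as replay inputs
and as regression anchors: a clean path in which no DLT occurs and the
trial stops early for safety of all combinations, and a path with six DLTs
that runs to the full 48 patients.  Each cohort records the externally
prescribed methadone doses (mg), the assigned baclofen doses (mg) and the
binary DLT outcomes, in patient order.

``*_PSAFE`` hold the published per-cohort posterior probabilities (percent)
that the high combination (120 mg methadone, 90 mg baclofen) has DLT risk
below 0.25 — the quantity driving the stop-for-safety-of-all-doses rule.
``DLT_PATH_FINAL_INTERVALS`` is the published end-of-trial dosing function of
the DLT path as closed methadone intervals per baclofen dose.
"""

from __future__ import annotations

# (methadone doses, baclofen doses, DLT indicators) per cohort of 3
CLEAN_PATH_COHORTS = [
    ((31, 47, 86), (10, 10, 10), (0, 0, 0)),
    ((66, 29, 44), (30, 30, 30), (0, 0, 0)),
    ((28, 56, 66), (60, 60, 60), (0, 0, 0)),
    ((18, 84, 83), (90, 90, 90), (0, 0, 0)),
    ((74, 30, 75), (90, 90, 90), (0, 0, 0)),
    ((82, 90, 10), (90, 90, 90), (0, 0, 0)),
    ((64, 60, 91), (90, 90, 90), (0, 0, 0)),
]

CLEAN_PATH_PSAFE = [54, 56, 62, 76, 83, 88, 93]

DLT_PATH_COHORTS = [
    ((29, 85, 44), (10, 10, 10), (0, 0, 0)),
    ((20, 71, 53), (30, 30, 30), (0, 0, 0)),
    ((37, 18, 22), (60, 60, 60), (0, 0, 0)),
    ((58, 47, 72), (90, 90, 90), (1, 0, 0)),
    ((45, 99, 66), (90, 60, 60), (0, 0, 0)),
    ((38, 70, 61), (90, 60, 90), (0, 0, 0)),
    ((75, 83, 36), (90, 60, 90), (0, 0, 0)),
    ((69, 56, 38), (90, 90, 90), (1, 0, 0)),
    ((48, 34, 67), (90, 90, 90), (1, 0, 0)),
    ((11, 68, 52), (90, 60, 90), (0, 0, 1)),
    ((47, 29, 79), (90, 90, 60), (0, 0, 0)),
    ((54, 80, 59), (90, 60, 60), (0, 1, 1)),
    ((57, 48, 59), (60, 60, 60), (0, 0, 0)),
    ((59, 20, 10), (60, 90, 90), (0, 0, 0)),
    ((44, 76, 79), (90, 60, 60), (0, 0, 0)),
    ((66, 19, 54), (60, 90, 90), (0, 0, 0)),
]

DLT_PATH_PSAFE = [54, 57, 58, 32, 42, 51, 60, 33, 21, 11, 14, 4, 5, 5, 7, 8]

# End-of-trial dosing function of the DLT path: baclofen dose ->
# closed methadone interval (mg).
DLT_PATH_FINAL_INTERVALS = {
    90: (10, 62),
    60: (63, 92),
    30: (93, 142),
    10: (143, 150),
}


def flatten(cohorts, upto: int | None = None):
    """Patient-level (m, b, y) triples for the first ``upto`` cohorts."""
    records = []
    for ms, bs, ys in cohorts[: upto if upto is not None else len(cohorts)]:
        records.extend(zip(ms, bs, ys))
    return records
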