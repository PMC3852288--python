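"""Shared fixtures: the fictitious four-criterion trial and its nine-patient
validation cohort covering every T/F/unknown combination of I1 and E1."""

from __future__ import annotations

import pytest

from trialeligibility.model import (
    Criterion,
    Decision,
    PatientRecord,
    TrialDefinition,
    TruthValue,
    parse_truth_value,
)

CRITERIA = ("I0", "I1", "E0", "E1")

# patient -> (I0, I1, E0, E1), expected decision, failed incl., matched
# excl., missing criteria
VALIDATION_ROWS = {
    "p0": (("T", "T", "F", "T"), Decision.NOT_ELIGIBLE, set(), {"E1"}, set()),
    "p1": (("T", "T", "F", "F"), Decision.ELIGIBLE, set(), set(), set()),
    "p2": (("T", "T", "F", "?"), Decision.UNDETERMINED, set(), set(), {"E1"}),
    "p3": (("T", "F", "F", "T"), Decision.NOT_ELIGIBLE, {"I1"}, {"E1"}, set()),
    "p4": (("T", "F", "F", "F"), Decision.NOT_ELIGIBLE, {"I1"}, set(), set()),
    "p5": (("T", "F", "F", "?"), Decision.NOT_ELIGIBLE, {"I1"}, set(), {"E1"}),
    "p6": (("T", "?", "F", "T"), Decision.NOT_ELIGIBLE, set(), {"E1"}, {"I1"}),
    "p7": (("T", "?", "F", "F"), Decision.UNDETERMINED, set(), set(), {"I1"}),
    "p8": (("T", "?", "F", "?"), Decision.UNDETERMINED, set(), set(), {"I1", "E1"}),
}


def record_from_symbols(patient_id: str, symbols) -> PatientRecord:
    statuses = {}
    for cid, sym in zip(CRITERIA, symbols):
        v = parse_truth_value(sym)
        if v is not TruthValue.UNKNOWN:
            statuses[cid] = v
    return PatientRecord(patient_id=patient_id, statuses=statuses)


@pytest.fixture(scope="session")
def fictitious_trial() -> TrialDefinition:
    return TrialDefinition(
        trial_id="fictitious", inclusion=("I0", "I1"), exclusion=("E0", "E1")
    )


@pytest.fixture(scope="session")
def registry() -> list[Criterion]:
    return [Criterion(id=c) for c in CRITERIA]


@pytest.fixture(scope="session")
def validation_cohort() -> list[PatientRecord]:
    return [
        record_from_symbols(pid, row[0]) for pid, row in VALIDATION_ROWS.items()
    ]
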