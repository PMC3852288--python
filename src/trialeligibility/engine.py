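"""Three-valued eligibility evaluation.

The open-world evaluator lifts the eligibility conjunction

    eligible  <=>  (AND_i I_i)  AND  (AND_j NOT E_j)

to strong Kleene logic over {true, false, unknown}: a conjunction is false
as soon as one conjunct is false, unknown if none is false but one is
unknown, and true otherwise.  The resulting decision distinguishes patients
who are provably eligible, provably not eligible (with the disqualifying
criteria as causes), and undetermined (with the exact missing criteria).

The closed-world baseline treats anything not provable as failed: a single
unknown status anywhere rejects the patient.  ``compare_policies`` returns
the patients the closed-world reading over-rejects.

``completion_oracle`` is an independent brute-force semantics: it
enumerates every classical completion of the unknown statuses and reports
eligible / not eligible only when all completions agree.  It exists as a
ground truth for testing the evaluator, not as a production path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import (
    Decision,
    EligibilityResult,
    PatientRecord,
    TrialDefinition,
    TruthValue,
    ValidationError,
)

__all__ = [
    "ClosedWorldDecision",
    "CohortClassification",
    "kleene_not",
    "kleene_and",
    "evaluate_open_world",
    "evaluate_closed_world",
    "completion_oracle",
    "classify_cohort",
    "compare_policies",
]


def kleene_not(v: TruthValue) -> TruthValue:
    """Strong Kleene negation: swaps true/false, preserves unknown."""
    if v is TruthValue.TRUE:
        return TruthValue.FALSE
    if v is TruthValue.FALSE:
        return TruthValue.TRUE
    return TruthValue.UNKNOWN


def kleene_and(vs: Iterable[TruthValue]) -> TruthValue:
    """Strong Kleene conjunction; the empty conjunction is true."""
    result = TruthValue.TRUE
    for v in vs:
        if v is TruthValue.FALSE:
            return TruthValue.FALSE
        if v is TruthValue.UNKNOWN:
            result = TruthValue.UNKNOWN
    return result


_DECISION_FOR = {
    TruthValue.TRUE: Decision.ELIGIBLE,
    TruthValue.FALSE: Decision.NOT_ELIGIBLE,
    TruthValue.UNKNOWN: Decision.UNDETERMINED,
}


def evaluate_open_world(
    trial: TrialDefinition, patient: PatientRecord
) -> EligibilityResult:
    """Evaluate a patient against a trial under the open-world assumption.

    Returns the three-valued decision plus cause sets: the inclusion
    criteria that are false, the exclusion criteria that are true, and the
    criteria whose status is unknown.  Decided (not-eligible) patients may
    still carry unknowns; these are reported because they identify what
    else could not be verified, but they play no role in the decision.
    """
    inc = {c: patient.status(c) for c in trial.inclusion}
    exc = {c: patient.status(c) for c in trial.exclusion}
    verdict = kleene_and(
        itertools.chain(inc.values(), (kleene_not(v) for v in exc.values()))
    )
    return EligibilityResult(
        patient_id=patient.patient_id,
        trial_id=trial.trial_id,
        decision=_DECISION_FOR[verdict],
        failed_inclusions=frozenset(
            c for c, v in inc.items() if v is TruthValue.FALSE
        ),
        matched_exclusions=frozenset(
            c for c, v in exc.items() if v is TruthValue.TRUE
        ),
        unknown_inclusions=frozenset(
            c for c, v in inc.items() if v is TruthValue.UNKNOWN
        ),
        unknown_exclusions=frozenset(
            c for c, v in exc.items() if v is TruthValue.UNKNOWN
        ),
    )


class ClosedWorldDecision:
    """Binary decisions of the negation-as-failure baseline."""

    INCLUDE = "INCLUDE"
    EXCLUDE = "EXCLUDE"


def evaluate_closed_world(trial: TrialDefinition, patient: PatientRecord) -> str:
    """Negation-as-failure baseline: a conjunct counts only if provable.

    INCLUDE iff every inclusion criterion is provably true and every
    exclusion criterion provably false; any unknown status anywhere makes
    the patient EXCLUDE.  This is the reading that over-estimates rejection
    on incomplete records.
    """
    ok = all(
        patient.status(c) is TruthValue.TRUE for c in trial.inclusion
    ) and all(patient.status(c) is TruthValue.FALSE for c in trial.exclusion)
    return ClosedWorldDecision.INCLUDE if ok else ClosedWorldDecision.EXCLUDE


_MAX_UNKNOWNS = 20


def completion_oracle(trial: TrialDefinition, patient: PatientRecord) -> Decision:
    """Brute-force three-valued semantics by enumerating completions.

    Every assignment of true/false to the patient's unknown statuses among
    the trial's criteria is evaluated classically; the verdict is ELIGIBLE
    if all completions are eligible, NOT_ELIGIBLE if none is, UNDETERMINED
    otherwise.  Refuses more than 20 unknowns (2^u completions).
    """
    unknowns = [
        c for c in trial.criteria if patient.status(c) is TruthValue.UNKNOWN
    ]
    if len(unknowns) > _MAX_UNKNOWNS:
        raise ValidationError(
            f"completion oracle limited to {_MAX_UNKNOWNS} unknown statuses; "
            f"got {len(unknowns)}"
        )

    def classical_eligible(assignment: dict[str, bool]) -> bool:
        def truth(c: str) -> bool:
            v = patient.status(c)
            if v is TruthValue.UNKNOWN:
                return assignment[c]
            return v is TruthValue.TRUE

        return all(truth(c) for c in trial.inclusion) and not any(
            truth(c) for c in trial.exclusion
        )

    outcomes = {
        classical_eligible(dict(zip(unknowns, bits)))
        for bits in itertools.product((True, False), repeat=len(unknowns))
    }
    if outcomes == {True}:
        return Decision.ELIGIBLE
    if outcomes == {False}:
        return Decision.NOT_ELIGIBLE
    return Decision.UNDETERMINED


@dataclass(frozen=True)
class CohortClassification:
    """Per-patient results plus per-decision counts for one trial."""

    trial_id: str
    results: tuple[EligibilityResult, ...]
    counts: dict[Decision, int]

    def __post_init__(self) -> None:
        tally = {d: 0 for d in Decision}
        for r in self.results:
            tally[r.decision] += 1
        if tally != self.counts:
            raise ValidationError("counts do not match results")


def classify_cohort(
    trial: TrialDefinition, patients: Sequence[PatientRecord]
) -> CohortClassification:
    """Open-world classification of a whole cohort, order preserved."""
    seen: set[str] = set()
    for p in patients:
        if p.patient_id in seen:
            raise ValidationError(f"duplicate patient id {p.patient_id!r}")
        seen.add(p.patient_id)
    results = tuple(evaluate_open_world(trial, p) for p in patients)
    counts = {d: 0 for d in Decision}
    for r in results:
        counts[r.decision] += 1
    return CohortClassification(trial_id=trial.trial_id, results=results, counts=counts)


def compare_policies(
    trial: TrialDefinition, patients: Sequence[PatientRecord]
) -> set[str]:
    """Patients the closed-world baseline over-rejects.

    Returns the ids for which negation-as-failure says EXCLUDE while the
    open-world evaluation is UNDETERMINED — the patients a closed-world
    screening would discard even though their eligibility is still open.
    """
    conflicts: set[str] = set()
    for p in patients:
        cw = evaluate_closed_world(trial, p)
        ow = evaluate_open_world(trial, p).decision
        if cw == ClosedWorldDecision.EXCLUDE and ow is Decision.UNDETERMINED:
            conflicts.add(p.patient_id)
    return conflicts
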