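"""Three-valued engine: connectives, open/closed-world evaluation, oracle.

The completion oracle (classical evaluation of every assignment of the
unknown statuses) is the independent ground truth: the Kleene evaluation
must agree with it on every reachable input.
"""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialeligibility.engine import (
    ClosedWorldDecision,
    classify_cohort,
    compare_policies,
    completion_oracle,
    evaluate_closed_world,
    evaluate_open_world,
    kleene_and,
    kleene_not,
)
from trialeligibility.model import (
    Decision,
    PatientRecord,
    TrialDefinition,
    TruthValue,
    ValidationError,
)

from conftest import VALIDATION_ROWS, record_from_symbols

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


@pytest.mark.parametrize("v,expected", [(T, F), (F, T), (U, U)])
def test_kleene_not(v, expected):
    assert kleene_not(v) is expected


@pytest.mark.parametrize(
    "vs,expected",
    [
        ([T, T, T, T], T),
        ([T, F, U], F),  # false dominates unknown
        ([T, U, T], U),
        ([], T),  # empty conjunction
        ([U, U], U),
        ([F], F),
    ],
)
def test_kleene_and(vs, expected):
    assert kleene_and(vs) is expected


@pytest.mark.parametrize("pid", sorted(VALIDATION_ROWS))
def test_open_world_reproduces_validation_table(pid, fictitious_trial):
    """Each of the nine reference patients gets the published decision and
    the published causes."""
    symbols, decision, failed, matched, missing = VALIDATION_ROWS[pid]
    result = evaluate_open_world(fictitious_trial, record_from_symbols(pid, symbols))
    assert result.decision is decision
    assert result.failed_inclusions == failed
    assert result.matched_exclusions == matched
    assert result.missing_criteria == missing


@pytest.mark.parametrize("pid", sorted(VALIDATION_ROWS))
def test_closed_world_includes_only_the_fully_satisfied_patient(pid, fictitious_trial):
    symbols, *_ = VALIDATION_ROWS[pid]
    got = evaluate_closed_world(fictitious_trial, record_from_symbols(pid, symbols))
    expected = (
        ClosedWorldDecision.INCLUDE if pid == "p1" else ClosedWorldDecision.EXCLUDE
    )
    assert got == expected


def test_compare_policies_finds_the_over_rejected_patients(
    fictitious_trial, validation_cohort
):
    assert compare_policies(fictitious_trial, validation_cohort) == {"p2", "p7", "p8"}


def test_compare_policies_empty_on_complete_information(fictitious_trial):
    complete = [
        record_from_symbols(f"q{i}", syms)
        for i, syms in enumerate(itertools.product("TF", repeat=4))
    ]
    assert compare_policies(fictitious_trial, complete) == set()


class TestCompletionOracle:
    def test_matches_validation_decisions(self, fictitious_trial, validation_cohort):
        for p in validation_cohort:
            expected = VALIDATION_ROWS[p.patient_id][1]
            assert completion_oracle(fictitious_trial, p) is expected

    def test_refuses_too_many_unknowns(self):
        trial = TrialDefinition("big", inclusion=tuple(f"I{i}" for i in range(25)))
        with pytest.raises(ValidationError, match="20"):
            completion_oracle(trial, PatientRecord(patient_id="p"))


def _all_trial_shapes(max_total=6):
    for total in range(max_total + 1):
        for n_inc in range(total + 1):
            yield n_inc, total - n_inc


def test_engine_equals_oracle_exhaustively_up_to_six_criteria():
    """For every inclusion/exclusion split with at most six criteria and
    every tri-valued status vector, the Kleene decision equals the
    enumerate-all-completions decision."""
    statuses = (T, F, U)
    for n_inc, n_exc in _all_trial_shapes(6):
        inc = tuple(f"I{i}" for i in range(n_inc))
        exc = tuple(f"E{j}" for j in range(n_exc))
        trial = TrialDefinition("t", inclusion=inc, exclusion=exc)
        for vector in itertools.product(statuses, repeat=n_inc + n_exc):
            patient = PatientRecord(
                patient_id="p",
                statuses={c: v for c, v in zip(inc + exc, vector) if v is not U},
            )
            assert (
                evaluate_open_world(trial, patient).decision
                is completion_oracle(trial, patient)
            ), (inc, exc, vector)


status_vectors = st.lists(st.sampled_from([T, F, U]), min_size=0, max_size=6)


@settings(max_examples=300, derandomize=True)
@given(vector=status_vectors, split=st.integers(min_value=0, max_value=6))
def test_closed_world_include_iff_open_world_eligible(vector, split):
    """The over-rejection theorem: negation-as-failure inclusion coincides
    with provable eligibility, so everything else is rejected even when
    merely undetermined."""
    split = min(split, len(vector))
    inc = tuple(f"I{i}" for i in range(split))
    exc = tuple(f"E{j}" for j in range(len(vector) - split))
    trial = TrialDefinition("t", inclusion=inc, exclusion=exc)
    patient = PatientRecord(
        patient_id="p",
        statuses={c: v for c, v in zip(inc + exc, vector) if v is not U},
    )
    cw = evaluate_closed_world(trial, patient)
    ow = evaluate_open_world(trial, patient).decision
    assert (cw == ClosedWorldDecision.INCLUDE) == (ow is Decision.ELIGIBLE)


@settings(max_examples=300, derandomize=True)
@given(
    vector=status_vectors,
    split=st.integers(min_value=0, max_value=6),
    data=st.data(),
)
def test_knowledge_monotonicity(vector, split, data):
    """Filling in an unknown status never flips a decided patient; it can
    only resolve an undetermined one."""
    split = min(split, len(vector))
    inc = tuple(f"I{i}" for i in range(split))
    exc = tuple(f"E{j}" for j in range(len(vector) - split))
    trial = TrialDefinition("t", inclusion=inc, exclusion=exc)
    statuses = {c: v for c, v in zip(inc + exc, vector) if v is not U}
    before = evaluate_open_world(
        trial, PatientRecord(patient_id="p", statuses=statuses)
    ).decision
    unknowns = [c for c in inc + exc if c not in statuses]
    if not unknowns:
        return
    cid = data.draw(st.sampled_from(unknowns))
    filled = dict(statuses, **{cid: data.draw(st.sampled_from([T, F]))})
    after = evaluate_open_world(
        trial, PatientRecord(patient_id="p", statuses=filled)
    ).decision
    if before is not Decision.UNDETERMINED:
        assert after is before


@settings(max_examples=200, derandomize=True)
@given(vector=status_vectors, split=st.integers(min_value=0, max_value=6), seed=st.integers(0, 2**16))
def test_permutation_invariance(vector, split, seed):
    import random

    split = min(split, len(vector))
    inc = list(f"I{i}" for i in range(split))
    exc = list(f"E{j}" for j in range(len(vector) - split))
    statuses = {c: v for c, v in zip(inc + exc, vector) if v is not U}
    patient = PatientRecord(patient_id="p", statuses=statuses)
    base = evaluate_open_world(
        TrialDefinition("t", inclusion=tuple(inc), exclusion=tuple(exc)), patient
    )
    rng = random.Random(seed)
    rng.shuffle(inc)
    rng.shuffle(exc)
    shuffled = evaluate_open_world(
        TrialDefinition("t", inclusion=tuple(inc), exclusion=tuple(exc)), patient
    )
    assert shuffled.decision is base.decision
    assert shuffled.failed_inclusions == base.failed_inclusions
    assert shuffled.matched_exclusions == base.matched_exclusions


class TestCohort:
    def test_counts_match_validation_table(self, fictitious_trial, validation_cohort):
        cls = classify_cohort(fictitious_trial, validation_cohort)
        assert cls.counts == {
            Decision.ELIGIBLE: 1,
            Decision.NOT_ELIGIBLE: 5,
            Decision.UNDETERMINED: 3,
        }
        assert [r.patient_id for r in cls.results] == [
            p.patient_id for p in validation_cohort
        ]

    def test_empty_cohort(self, fictitious_trial):
        cls = classify_cohort(fictitious_trial, [])
        assert all(n == 0 for n in cls.counts.values())

    def test_fully_known_cohort_has_no_undetermined(self, fictitious_trial):
        complete = [
            record_from_symbols(f"q{i}", syms)
            for i, syms in enumerate(itertools.product("TF", repeat=4))
        ]
        cls = classify_cohort(fictitious_trial, complete)
        assert cls.counts[Decision.UNDETERMINED] == 0

    def test_duplicate_patient_ids_rejected(self, fictitious_trial):
        twice = [PatientRecord(patient_id="p"), PatientRecord(patient_id="p")]
        with pytest.raises(ValidationError, match="duplicate"):
            classify_cohort(fictitious_trial, twice)


def test_compare_policies_agrees_with_oracle_on_random_cohort(fictitious_trial):
    """Cross-check: the conflict set is exactly {closed-world EXCLUDE and
    oracle UNDETERMINED}, with the oracle computed independently."""
    import random

    rng = random.Random(20130917)
    cohort = []
    for i in range(200):
        symbols = [rng.choice("TF?") for _ in range(4)]
        cohort.append(record_from_symbols(f"r{i}", symbols))
    expected = {
        p.patient_id
        for p in cohort
        if evaluate_closed_world(fictitious_trial, p) == ClosedWorldDecision.EXCLUDE
        and completion_oracle(fictitious_trial, p) is Decision.UNDETERMINED
    }
    assert compare_policies(fictitious_trial, cohort) == expected
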