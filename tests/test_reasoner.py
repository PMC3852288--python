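"""Entailment classification of the compiled ontologies, and the
engine-vs-entailment cross-check.

The classifier works purely on the serialized axioms, so agreement with
the Kleene engine is a genuine two-route check of the open-world
semantics.
"""

import itertools

import pytest

from trialeligibility.engine import evaluate_open_world
from trialeligibility.model import (
    Criterion,
    Decision,
    PatientRecord,
    TrialDefinition,
    TruthValue,
)
from trialeligibility.owl import build_ontology, serialize_ontology
from trialeligibility.reasoner import (
    InconsistentOntologyError,
    classify_with_reasoner,
    crosscheck_engine_vs_reasoner,
    parse_ontology,
)

from conftest import CRITERIA, record_from_symbols

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


@pytest.fixture(scope="module")
def validation_classification(fictitious_trial, registry, validation_cohort):
    model = build_ontology(
        [fictitious_trial], registry, validation_cohort
    )
    return classify_with_reasoner(serialize_ontology(model, "rdfxml"))


def test_fully_known_eligible_patient_is_inferred_into_include(
    validation_classification,
):
    m = validation_classification.memberships["p1"]
    assert m["Ct_fictitious_include"] is True


def test_matched_exclusion_patients_land_in_the_exclusion_class(
    validation_classification,
):
    cls = "Ct_fictitious_exclude_at_least_one_exclusion_criterion"
    members = {
        pid
        for pid, m in validation_classification.memberships.items()
        if m.get(cls)
    }
    assert members == {"p0", "p3", "p6"}


def test_failed_inclusion_patients_land_in_the_failed_class(
    validation_classification,
):
    cls = "Ct_fictitious_exclude_at_least_one_failed_inclusion_criterion"
    members = {
        pid
        for pid, m in validation_classification.memberships.items()
        if m.get(cls)
    }
    assert members == {"p3", "p4", "p5"}


def test_undetermined_patients_are_in_no_trial_class(validation_classification):
    for pid in ("p2", "p7", "p8"):
        assert not any(validation_classification.memberships[pid].values())
        assert (
            validation_classification.decisions[pid]["Ct_fictitious"]
            is Decision.UNDETERMINED
        )


def test_no_patient_with_unknown_relevant_criterion_is_included(
    fictitious_trial, registry
):
    """Open-world soundness: an unknown status blocks inferred inclusion."""
    cohort = []
    for i, vector in enumerate(itertools.product("TF?", repeat=4)):
        if "?" in vector:
            cohort.append(record_from_symbols(f"x{i}", vector))
    model = build_ontology([fictitious_trial], registry, cohort)
    classification = classify_with_reasoner(serialize_ontology(model))
    for pid, m in classification.memberships.items():
        assert m["Ct_fictitious_include"] is False


def test_inconsistent_assertion_is_reported():
    registry = [Criterion(id="I0")]
    trial = TrialDefinition(trial_id="t", inclusion=("I0",))
    model = build_ontology([trial], registry, [])
    document = serialize_ontology(model, "turtle")
    # forge an individual asserted into both C_I0 and Not_C_I0
    document += (
        '\n:broken a owl:NamedIndividual, :Criterion, :C_I0, :Not_C_I0 .\n'
    )
    with pytest.raises(InconsistentOntologyError, match="C_I0"):
        classify_with_reasoner(document, format="turtle")


@pytest.mark.parametrize("fmt", ["rdfxml", "turtle", "ofn"])
def test_all_serializations_parse_to_the_same_axioms(
    fictitious_trial, registry, validation_cohort, fmt
):
    model = build_ontology([fictitious_trial], registry, validation_cohort)
    po = parse_ontology(serialize_ontology(model, fmt), format=fmt)
    assert po.root == "Criterion"
    assert set(po.notc_for) == {f"C_{c}" for c in CRITERIA}
    assert set(po.individuals) == {p.patient_id for p in validation_cohort}
    assert po.individuals["p1"] >= {"C_I0", "C_I1", "Not_C_E0", "Not_C_E1"}


def test_crosscheck_validation_cohort_has_no_deviations(
    fictitious_trial, registry, validation_cohort
):
    assert (
        crosscheck_engine_vs_reasoner([fictitious_trial], registry, validation_cohort)
        == []
    )


@pytest.mark.parametrize("fmt", ["turtle", "ofn"])
def test_crosscheck_holds_across_serialization_formats(
    fictitious_trial, registry, validation_cohort, fmt
):
    assert (
        crosscheck_engine_vs_reasoner(
            [fictitious_trial], registry, validation_cohort, format=fmt
        )
        == []
    )


def test_crosscheck_exhaustive_on_small_trials():
    """Every trial shape with up to four criteria, every tri-valued record:
    entailment classification equals the engine."""
    for n_inc, n_exc in [(0, 0), (1, 0), (0, 1), (2, 1), (1, 2), (2, 2)]:
        inc = tuple(f"I{i}" for i in range(n_inc))
        exc = tuple(f"E{j}" for j in range(n_exc))
        registry = [Criterion(id=c) for c in inc + exc]
        trial = TrialDefinition(trial_id="t", inclusion=inc, exclusion=exc)
        cohort = [
            record_from_symbols_for(inc + exc, f"v{i}", vector)
            for i, vector in enumerate(
                itertools.product("TF?", repeat=n_inc + n_exc)
            )
        ]
        assert crosscheck_engine_vs_reasoner([trial], registry, cohort) == []


def record_from_symbols_for(criteria, pid, symbols):
    from trialeligibility.model import parse_truth_value

    statuses = {}
    for cid, sym in zip(criteria, symbols):
        v = parse_truth_value(sym)
        if v is not U:
            statuses[cid] = v
    return PatientRecord(patient_id=pid, statuses=statuses)


def test_crosscheck_on_random_six_criterion_cohort():
    """Fifty random tri-valued records over a six-criterion trial agree
    between the two routes."""
    import random

    rng = random.Random(414)
    inc = ("I0", "I1", "I2")
    exc = ("E0", "E1", "E2")
    registry = [Criterion(id=c) for c in inc + exc]
    trial = TrialDefinition(trial_id="wide", inclusion=inc, exclusion=exc)
    cohort = [
        record_from_symbols_for(
            inc + exc, f"r{i}", [rng.choice("TF?") for _ in range(6)]
        )
        for i in range(50)
    ]
    assert crosscheck_engine_vs_reasoner([trial], registry, cohort) == []


def test_crosscheck_multiple_trials_sharing_criteria():
    """A criterion may be inclusion for one trial and exclusion for
    another; both trials are classified from the same ontology."""
    registry = [Criterion(id=c) for c in ("A", "B", "C")]
    trials = [
        TrialDefinition(trial_id="t1", inclusion=("A", "B"), exclusion=("C",)),
        TrialDefinition(trial_id="t2", inclusion=("C",), exclusion=("A",)),
    ]
    cohort = [
        record_from_symbols_for(("A", "B", "C"), f"m{i}", vector)
        for i, vector in enumerate(itertools.product("TF?", repeat=3))
    ]
    assert crosscheck_engine_vs_reasoner(trials, registry, cohort) == []
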