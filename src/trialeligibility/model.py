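"""Domain types for clinical-trial eligibility under partially-known information.

A trial is an ordered pair of inclusion and exclusion criterion lists; a
patient record maps criterion ids to three-valued statuses (true / false /
unknown).  A criterion id absent from a record means "unknown" — absence of
information, never absence of the condition.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TruthValue",
    "Decision",
    "Criterion",
    "TrialDefinition",
    "PatientRecord",
    "EligibilityResult",
    "BindingRule",
    "Comparator",
    "ValidationError",
    "UnsatisfiableTrialError",
    "UnknownCriterionError",
    "TruthValueParseError",
    "normalize_id",
    "parse_truth_value",
    "validate_trial",
]


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class UnsatisfiableTrialError(ValidationError):
    """The same criterion appears as both inclusion and exclusion."""


class UnknownCriterionError(ValidationError):
    """A criterion id is not present in the supplied registry."""


class TruthValueParseError(ValueError):
    """A token is outside the documented truth-value alphabet."""


class TruthValue(enum.Enum):
    """Three-valued criterion status: met, not met, or not known."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard
        raise TypeError(
            "TruthValue is three-valued; use explicit comparisons, not bool()"
        )


class Decision(enum.Enum):
    """Eligibility decision for one patient and one trial."""

    ELIGIBLE = "eligible"
    NOT_ELIGIBLE = "not eligible"
    UNDETERMINED = "potentially eligible"


_TRUE_TOKENS = frozenset({"t", "true", "yes", "1"})
_FALSE_TOKENS = frozenset({"f", "false", "no", "0"})
_UNKNOWN_TOKENS = frozenset({"?", "u", "unknown", "not specified", ""})


def parse_truth_value(text: str) -> TruthValue:
    """Map a textual status token to a :class:`TruthValue`.

    Case-insensitive.  ``T/true/yes/1`` are true; ``F/false/no/0`` are
    false; ``?/U/unknown/not specified`` and the empty string are unknown
    (absence of information).  Anything else raises
    :class:`TruthValueParseError`.
    """
    token = text.strip().lower()
    if token in _TRUE_TOKENS:
        return TruthValue.TRUE
    if token in _FALSE_TOKENS:
        return TruthValue.FALSE
    if token in _UNKNOWN_TOKENS:
        return TruthValue.UNKNOWN
    raise TruthValueParseError(f"unrecognized truth-value token: {text!r}")


_WS = re.compile(r"\s+")


def normalize_id(raw: str) -> str:
    """Trim and replace internal whitespace with underscores.

    Criterion and trial ids become OWL class-name fragments, so they must
    survive as IRI components.
    """
    token = _WS.sub("_", raw.strip())
    if not token:
        raise ValidationError("id must be non-empty")
    return token


@dataclass(frozen=True)
class Criterion:
    """An atomic eligibility condition, identified by a unique id."""

    id: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", normalize_id(self.id))


@dataclass(frozen=True)
class TrialDefinition:
    """A clinical trial: ordered inclusion and exclusion criterion lists.

    A patient is eligible iff every inclusion criterion is met and no
    exclusion criterion is met.  Either list may be empty.  The same id in
    both lists makes the trial unsatisfiable and is rejected.
    """

    trial_id: str
    inclusion: tuple[str, ...] = ()
    exclusion: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "trial_id", normalize_id(self.trial_id))
        object.__setattr__(
            self, "inclusion", tuple(normalize_id(c) for c in self.inclusion)
        )
        object.__setattr__(
            self, "exclusion", tuple(normalize_id(c) for c in self.exclusion)
        )
        for name, ids in (("inclusion", self.inclusion), ("exclusion", self.exclusion)):
            seen: set[str] = set()
            for cid in ids:
                if cid in seen:
                    raise ValidationError(
                        f"duplicate criterion {cid!r} in {name} list of trial "
                        f"{self.trial_id!r}"
                    )
                seen.add(cid)
        overlap = set(self.inclusion) & set(self.exclusion)
        if overlap:
            raise UnsatisfiableTrialError(
                f"unsatisfiable trial {self.trial_id!r}: criteria "
                f"{sorted(overlap)} appear as both inclusion and exclusion"
            )

    @property
    def criteria(self) -> tuple[str, ...]:
        return self.inclusion + self.exclusion


def validate_trial(trial: TrialDefinition, registry: Iterable[Criterion]) -> TrialDefinition:
    """Check a trial against a criterion registry and return it unchanged.

    The structural invariants (duplicate-free lists, disjoint lists) are
    already enforced by the :class:`TrialDefinition` constructor; this adds
    the referential check that every id exists in ``registry``.  Idempotent.
    """
    known = {c.id for c in registry}
    for cid in trial.criteria:
        if cid not in known:
            raise UnknownCriterionError(
                f"trial {trial.trial_id!r} references unknown criterion {cid!r}"
            )
    return trial


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient criterion statuses.

    ``statuses`` maps criterion id to a :class:`TruthValue`.  An id absent
    from the mapping is semantically UNKNOWN; explicit UNKNOWN entries are
    permitted and equivalent.
    """

    patient_id: str
    statuses: Mapping[str, TruthValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_id", normalize_id(self.patient_id))
        object.__setattr__(
            self,
            "statuses",
            {normalize_id(k): v for k, v in dict(self.statuses).items()},
        )

    def status(self, criterion_id: str) -> TruthValue:
        """Status of a criterion; absent entries are UNKNOWN."""
        return self.statuses.get(criterion_id, TruthValue.UNKNOWN)

    def check_registry(self, registry: Iterable[Criterion]) -> None:
        known = {c.id for c in registry}
        for cid in self.statuses:
            if cid not in known:
                raise UnknownCriterionError(
                    f"patient {self.patient_id!r} carries status for unknown "
                    f"criterion {cid!r}"
                )


@dataclass(frozen=True)
class EligibilityResult:
    """Decision for one patient against one trial, with its causes.

    * NOT_ELIGIBLE iff at least one inclusion criterion is false or one
      exclusion criterion is true (the union of the two cause sets).
    * ELIGIBLE iff all four sets are empty: every criterion decided the
      right way.
    * UNDETERMINED iff nothing disqualifies the patient but at least one
      relevant criterion is unknown.
    """

    patient_id: str
    trial_id: str
    decision: Decision
    failed_inclusions: frozenset[str] = frozenset()
    matched_exclusions: frozenset[str] = frozenset()
    unknown_inclusions: frozenset[str] = frozenset()
    unknown_exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        disqualifying = self.failed_inclusions | self.matched_exclusions
        unknowns = self.unknown_inclusions | self.unknown_exclusions
        if self.decision is Decision.NOT_ELIGIBLE:
            ok = bool(disqualifying)
        elif self.decision is Decision.ELIGIBLE:
            ok = not disqualifying and not unknowns
        else:
            ok = not disqualifying and bool(unknowns)
        if not ok:
            raise ValidationError(
                f"inconsistent result for patient {self.patient_id!r}: "
                f"decision {self.decision.name} with causes "
                f"failed={sorted(self.failed_inclusions)} "
                f"matched={sorted(self.matched_exclusions)} "
                f"unknown={sorted(unknowns)}"
            )

    @property
    def missing_criteria(self) -> frozenset[str]:
        return self.unknown_inclusions | self.unknown_exclusions


class Comparator(enum.Enum):
    """Comparators available to binding rules."""

    EQ = "eq"
    NE = "ne"
    LT = "lt"
    LE = "le"
    GT = "gt"
    GE = "ge"
    IN = "in"
    NOT_IN = "not_in"
    PRESENT = "present"
    ABSENT = "absent"


_ORDERING = frozenset({Comparator.LT, Comparator.LE, Comparator.GT, Comparator.GE})
_NO_OPERAND = frozenset({Comparator.PRESENT, Comparator.ABSENT})
_SET_OPERAND = frozenset({Comparator.IN, Comparator.NOT_IN})


@dataclass(frozen=True)
class BindingRule:
    """Derivation of one criterion's status from one patient-table field.

    Ordering comparators require a numeric operand; ``present``/``absent``
    take none and test field availability itself, so they always decide.
    """

    criterion_id: str
    field: str
    comparator: Comparator
    operand: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion_id", normalize_id(self.criterion_id))
        if isinstance(self.comparator, str):
            object.__setattr__(self, "comparator", Comparator(self.comparator))
        if self.comparator in _NO_OPERAND:
            if self.operand is not None:
                raise ValidationError(
                    f"comparator {self.comparator.value!r} takes no operand"
                )
        elif self.operand is None:
            raise ValidationError(
                f"comparator {self.comparator.value!r} requires an operand"
            )
        if self.comparator in _ORDERING and not isinstance(
            self.operand, (int, float)
        ):
            raise ValidationError(
                f"ordering comparator {self.comparator.value!r} requires a "
                f"numeric operand, got {self.operand!r}"
            )
        if self.comparator in _SET_OPERAND:
            if isinstance(self.operand, (str, bytes)) or not isinstance(
                self.operand, Iterable
            ):
                raise ValidationError(
                    f"comparator {self.comparator.value!r} requires a set operand"
                )
            object.__setattr__(self, "operand", frozenset(self.operand))
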