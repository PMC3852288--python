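"""Derive three-valued criterion statuses from raw patient field tables.

Each binding rule ties one criterion to one column through a comparator
(eq/ne/lt/le/gt/ge/in/not_in/present/absent).  A missing cell yields
UNKNOWN — except for ``present``/``absent``, which test availability itself
and therefore always decide.  Missing-cell encodings recognized in tables:
empty string, "NA", "not specified", "?" and "unknown", case-insensitively.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    BindingRule,
    Comparator,
    PatientRecord,
    TruthValue,
    ValidationError,
)

__all__ = ["MISSING_TOKENS", "is_missing", "evaluate_binding", "bind_cohort"]

MISSING_TOKENS = frozenset({"", "na", "not specified", "?", "unknown"})


def is_missing(value: object) -> bool:
    """True if a cell encodes absence of information."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in MISSING_TOKENS:
        return True
    return False


class DataError(ValueError):
    """A cell value is incompatible with its rule's comparator."""


def _as_number(value: object, rule: BindingRule, patient_id: str) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    try:
        return float(str(value).strip())
    except ValueError:
        raise DataError(
            f"patient {patient_id!r}: field {rule.field!r} value {value!r} is "
            f"not numeric (required by comparator {rule.comparator.value!r})"
        ) from None


def _equals(operand: object, value: object) -> bool:
    # type-faithful equality: numeric when the operand is a number (so
    # "7" == 7.0), string comparison otherwise; a cell that cannot be
    # coerced to the operand's type is simply unequal
    if isinstance(operand, (int, float)) and not isinstance(operand, bool):
        try:
            return float(str(value).strip()) == float(operand)
        except ValueError:
            return False
    return str(value).strip() == str(operand)


def evaluate_binding(
    rule: BindingRule, row: Mapping[str, object], patient_id: str = "?"
) -> TruthValue:
    """Apply one rule to one patient row.

    A missing or absent field is UNKNOWN for every comparator except
    ``present``/``absent``.  Ordering comparators require a numeric cell.
    """
    raw = row.get(rule.field)
    missing = rule.field not in row or is_missing(raw)

    if rule.comparator is Comparator.PRESENT:
        return TruthValue.FALSE if missing else TruthValue.TRUE
    if rule.comparator is Comparator.ABSENT:
        return TruthValue.TRUE if missing else TruthValue.FALSE
    if missing:
        return TruthValue.UNKNOWN

    cmp = rule.comparator
    if cmp in (Comparator.LT, Comparator.LE, Comparator.GT, Comparator.GE):
        x = _as_number(raw, rule, patient_id)
        bound = float(rule.operand)  # type: ignore[arg-type]
        outcome = {
            Comparator.LT: x < bound,
            Comparator.LE: x <= bound,
            Comparator.GT: x > bound,
            Comparator.GE: x >= bound,
        }[cmp]
    elif cmp in (Comparator.EQ, Comparator.NE):
        outcome = _equals(rule.operand, raw)
        if cmp is Comparator.NE:
            outcome = not outcome
    else:  # IN / NOT_IN over a frozenset operand
        outcome = any(_equals(member, raw) for member in rule.operand)  # type: ignore[union-attr]
        if cmp is Comparator.NOT_IN:
            outcome = not outcome
    return TruthValue.TRUE if outcome else TruthValue.FALSE


def bind_cohort(
    rules: Sequence[BindingRule], table: pd.DataFrame
) -> list[PatientRecord]:
    """Apply every rule to every row of a patient field table.

    The table is indexed by patient id (or carries a ``patient_id``
    column).  Criteria without rules are simply absent from the resulting
    records, i.e. UNKNOWN.  At most one rule per criterion.
    """
    seen: set[str] = set()
    for r in rules:
        if r.criterion_id in seen:
            raise ValidationError(
                f"two binding rules for criterion {r.criterion_id!r}"
            )
        seen.add(r.criterion_id)

    df = table
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    if df.index.has_duplicates:
        raise ValidationError("duplicate patient ids in field table")

    records = []
    for pid, row in df.iterrows():
        mapping = row.to_dict()
        statuses = {}
        for rule in rules:
            v = evaluate_binding(rule, mapping, patient_id=str(pid))
            if v is not TruthValue.UNKNOWN:
                statuses[rule.criterion_id] = v
        records.append(PatientRecord(patient_id=str(pid), statuses=statuses))
    return records
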