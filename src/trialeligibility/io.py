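"""File formats: trial definitions, patient statuses, binding rules, tables.

Trial definitions are YAML or JSON documents::

    trial_id: prostate_ct1
    inclusion: [I0, I1]
    exclusion: [E0, E1]
    labels:            # optional
      I0: evidence of a prostate adenocarcinoma

Patient statuses are CSV with a ``patient_id`` column followed by one
column per criterion id; cells use the truth-value alphabet
(T/F/?/yes/no/not specified/...; an empty cell is unknown).

Binding rules are a YAML list of ``{criterion, field, comparator,
operand}``.  Field tables are CSV with a ``patient_id`` column; empty
cells, ``NA`` and ``not specified`` encode missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .engine import CohortClassification
from .model import (
    BindingRule,
    Criterion,
    PatientRecord,
    TrialDefinition,
    TruthValue,
    ValidationError,
    parse_truth_value,
)

__all__ = [
    "load_trials",
    "load_patient_statuses",
    "save_patient_statuses",
    "load_binding_rules",
    "load_field_table",
    "registry_from_trials",
    "classification_to_frame",
    "classification_to_json",
]


def _load_document(path: str | Path) -> object:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_trials(path: str | Path) -> list[TrialDefinition]:
    """Load one trial or a list of trials from a YAML/JSON file."""
    doc = _load_document(path)
    if isinstance(doc, dict) and "trials" in doc:
        doc = doc["trials"]
    if isinstance(doc, dict):
        doc = [doc]
    if not isinstance(doc, list):
        raise ValidationError(f"cannot read trial definitions from {path}")
    trials = []
    for entry in doc:
        trials.append(
            TrialDefinition(
                trial_id=str(entry["trial_id"]),
                inclusion=tuple(str(c) for c in entry.get("inclusion", []) or ()),
                exclusion=tuple(str(c) for c in entry.get("exclusion", []) or ()),
            )
        )
    return trials


def registry_from_trials(
    trials: Iterable[TrialDefinition],
    extra: Iterable[str] = (),
) -> list[Criterion]:
    """Build a criterion registry from the ids the trials reference."""
    seen: dict[str, Criterion] = {}
    for t in trials:
        for cid in t.criteria:
            seen.setdefault(cid, Criterion(id=cid))
    for cid in extra:
        c = Criterion(id=str(cid))
        seen.setdefault(c.id, c)
    return list(seen.values())


def load_patient_statuses(path: str | Path) -> list[PatientRecord]:
    """Read a cohort's criterion statuses from CSV.

    Every non-``patient_id`` column is a criterion; unknown cells (``?``,
    ``U``, ``not specified``, empty) leave the criterion out of the record.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column patient_id")
    criteria = [c for c in df.columns if c != "patient_id"]
    records = []
    for _, row in df.iterrows():
        statuses = {}
        for cid in criteria:
            v = parse_truth_value(str(row[cid]))
            if v is not TruthValue.UNKNOWN:
                statuses[cid] = v
        records.append(PatientRecord(patient_id=str(row["patient_id"]), statuses=statuses))
    return records


_CELL = {TruthValue.TRUE: "T", TruthValue.FALSE: "F", TruthValue.UNKNOWN: "?"}


def save_patient_statuses(
    records: Iterable[PatientRecord],
    criteria: Iterable[str],
    path: str | Path,
) -> None:
    """Write a cohort back to the status-CSV format (T / F / ?)."""
    criteria = list(criteria)
    rows = [
        {"patient_id": r.patient_id, **{c: _CELL[r.status(c)] for c in criteria}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", *criteria]).to_csv(path, index=False)


def load_binding_rules(path: str | Path) -> list[BindingRule]:
    """Read a YAML/JSON list of binding rules."""
    doc = _load_document(path)
    if isinstance(doc, dict) and "rules" in doc:
        doc = doc["rules"]
    if not isinstance(doc, list):
        raise ValidationError(f"cannot read binding rules from {path}")
    rules = []
    for entry in doc:
        rules.append(
            BindingRule(
                criterion_id=str(entry["criterion"]),
                field=str(entry["field"]),
                comparator=str(entry["comparator"]),
                operand=entry.get("operand"),
            )
        )
    return rules


def load_field_table(path: str | Path) -> pd.DataFrame:
    """Read a raw patient field table (CSV, ``patient_id`` column required).

    Cells are kept as strings; the missing-value encodings are interpreted
    downstream so that "NA" never silently collides with a category name.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column patient_id")
    if df["patient_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate patient ids")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate column names")
    return df


def classification_to_frame(classification: CohortClassification) -> pd.DataFrame:
    """One row per patient: decision plus semicolon-joined cause lists."""
    rows = []
    for r in classification.results:
        rows.append(
            {
                "patient_id": r.patient_id,
                "trial_id": r.trial_id,
                "decision": r.decision.value,
                "failed_inclusions": ";".join(sorted(r.failed_inclusions)),
                "matched_exclusions": ";".join(sorted(r.matched_exclusions)),
                "missing_criteria": ";".join(sorted(r.missing_criteria)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "trial_id",
            "decision",
            "failed_inclusions",
            "matched_exclusions",
            "missing_criteria",
        ],
    )


def classification_to_json(classification: CohortClassification) -> str:
    """JSON export of a cohort classification."""
    payload = {
        "trial_id": classification.trial_id,
        "counts": {d.value: n for d, n in classification.counts.items()},
        "results": [
            {
                "patient_id": r.patient_id,
                "decision": r.decision.value,
                "failed_inclusions": sorted(r.failed_inclusions),
                "matched_exclusions": sorted(r.matched_exclusions),
                "unknown_inclusions": sorted(r.unknown_inclusions),
                "unknown_exclusions": sorted(r.unknown_exclusions),
            }
            for r in classification.results
        ],
    }
    return json.dumps(payload, indent=2)
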