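"""Missingness statistics, per-trial field reports, and screening reports.

All fractions are kept at full precision internally and rendered to two
decimals.  Decisions render with the screening vocabulary: "eligible",
"not eligible", "potentially eligible".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binding import is_missing
from .engine import CohortClassification
from .model import (
    BindingRule,
    Decision,
    TrialDefinition,
    ValidationError,
)

__all__ = [
    "MissingnessStats",
    "TrialFieldCounts",
    "missingness_stats",
    "trial_field_report",
    "render_trial_field_report",
    "screening_report",
    "render_screening_report",
]


def _missing_mask(table: pd.DataFrame) -> pd.DataFrame:
    df = table
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    return df.map(is_missing)


@dataclass(frozen=True)
class MissingnessStats:
    """Counts of unspecified values in a patient field table."""

    total_cells: int
    missing_cells: int
    missing_fraction: float
    per_field_missing: dict[str, int]
    always_known_fields: tuple[str, ...]
    mean_missing_per_record: float

    def render(self) -> str:
        lines = [
            f"fields: {len(self.per_field_missing)}",
            f"total values: {self.total_cells}",
            f"unspecified values: {self.missing_cells} "
            f"({100 * self.missing_fraction:.2f}%)",
            f"mean unspecified fields per record: "
            f"{self.mean_missing_per_record:.2f}",
            f"systematically filled fields: {len(self.always_known_fields)}",
        ]
        return "\n".join(lines)


def missingness_stats(table: pd.DataFrame) -> MissingnessStats:
    """Quantify the unspecified values of a field table.

    A field is "always known" when it is filled for every patient.  The
    mean missing per record is in fields, not a fraction.
    """
    mask = _missing_mask(table)
    if mask.size == 0:
        raise ValidationError("missingness statistics undefined on an empty table")
    per_field = mask.sum(axis=0)
    missing = int(per_field.sum())
    n_rows = mask.shape[0]
    return MissingnessStats(
        total_cells=int(mask.size),
        missing_cells=missing,
        missing_fraction=missing / mask.size,
        per_field_missing={str(c): int(per_field[c]) for c in mask.columns},
        always_known_fields=tuple(
            str(c) for c in mask.columns if per_field[c] == 0
        ),
        mean_missing_per_record=missing / n_rows,
    )


@dataclass(frozen=True)
class TrialFieldCounts:
    """Field composition and completeness of one trial's bound criteria."""

    trial_id: str
    n_inclusion_fields: int
    n_exclusion_fields: int
    n_common_fields: int
    missing_fraction: float
    n_patients_all_inclusion_known: int
    n_patients_all_exclusion_known: int
    n_patients_all_known: int


def trial_field_report(
    trials: Sequence[TrialDefinition],
    rules: Sequence[BindingRule],
    table: pd.DataFrame,
) -> list[TrialFieldCounts]:
    """Per-trial report of bound fields and their missingness.

    "Common fields" are fields referenced both by a rule bound to one of
    the trial's inclusion criteria and by a rule bound to one of its
    exclusion criteria.  Completeness counts the patients with every field
    of the relevant side filled.
    """
    mask = _missing_mask(table)
    field_of: dict[str, str] = {}
    for r in rules:
        if r.criterion_id in field_of:
            raise ValidationError(f"two rules for criterion {r.criterion_id!r}")
        field_of[r.criterion_id] = r.field
        if r.field not in mask.columns:
            raise ValidationError(f"rule field {r.field!r} absent from table")
    report = []
    for trial in trials:
        inc_fields = {field_of[c] for c in trial.inclusion if c in field_of}
        exc_fields = {field_of[c] for c in trial.exclusion if c in field_of}
        all_fields = sorted(inc_fields | exc_fields)
        sub = mask[all_fields] if all_fields else mask.iloc[:, :0]
        total = sub.size
        inc_known = (
            (~mask[sorted(inc_fields)].any(axis=1)).sum() if inc_fields else len(mask)
        )
        exc_known = (
            (~mask[sorted(exc_fields)].any(axis=1)).sum() if exc_fields else len(mask)
        )
        all_known = (~sub.any(axis=1)).sum() if all_fields else len(mask)
        report.append(
            TrialFieldCounts(
                trial_id=trial.trial_id,
                n_inclusion_fields=len(inc_fields),
                n_exclusion_fields=len(exc_fields),
                n_common_fields=len(inc_fields & exc_fields),
                missing_fraction=(float(sub.sum().sum()) / total) if total else 0.0,
                n_patients_all_inclusion_known=int(inc_known),
                n_patients_all_exclusion_known=int(exc_known),
                n_patients_all_known=int(all_known),
            )
        )
    return report


def render_trial_field_report(report: Sequence[TrialFieldCounts]) -> str:
    """Plain-text table, one column per trial."""
    rows = [
        ("Nb inclusion fields", lambda c: str(c.n_inclusion_fields)),
        ("Nb exclusion fields", lambda c: str(c.n_exclusion_fields)),
        ("Nb common fields", lambda c: str(c.n_common_fields)),
        ("Missing values", lambda c: f"{100 * c.missing_fraction:.2f}%"),
        (
            "Nb patients with all inclusion fields known",
            lambda c: str(c.n_patients_all_inclusion_known),
        ),
        (
            "Nb patients with all exclusion fields known",
            lambda c: str(c.n_patients_all_exclusion_known),
        ),
        (
            "Nb patients with all fields known",
            lambda c: str(c.n_patients_all_known),
        ),
    ]
    width = max(len(label) for label, _ in rows)
    header = " " * width + "\t" + "\t".join(c.trial_id for c in report)
    lines = [header]
    for label, fn in rows:
        lines.append(label.ljust(width) + "\t" + "\t".join(fn(c) for c in report))
    return "\n".join(lines)


def screening_report(
    classification: CohortClassification,
    conflicts: Iterable[str] = (),
) -> dict:
    """JSON-serializable screening report for one trial.

    Lists counts per decision, the exact missing criteria of every
    potentially-eligible patient, the causes of every rejection, and the
    patients a closed-world policy would over-reject.
    """
    undetermined = {
        r.patient_id: sorted(r.missing_criteria)
        for r in classification.results
        if r.decision is Decision.UNDETERMINED
    }
    rejected = {
        r.patient_id: {
            "failed_inclusions": sorted(r.failed_inclusions),
            "matched_exclusions": sorted(r.matched_exclusions),
        }
        for r in classification.results
        if r.decision is Decision.NOT_ELIGIBLE
    }
    return {
        "trial_id": classification.trial_id,
        "n_patients": len(classification.results),
        "counts": {d.value: n for d, n in classification.counts.items()},
        "potentially_eligible_missing_criteria": undetermined,
        "not_eligible_causes": rejected,
        "closed_world_over_rejections": sorted(conflicts),
    }


def render_screening_report(report: Mapping) -> str:
    """Human-readable rendering of a screening report."""
    counts = report["counts"]
    n = report["n_patients"]
    lines = [f"Trial {report['trial_id']}: {n} patients screened"]
    for name in (
        Decision.ELIGIBLE.value,
        Decision.UNDETERMINED.value,
        Decision.NOT_ELIGIBLE.value,
    ):
        count = counts.get(name, 0)
        pct = f" ({100 * count / n:.2f}%)" if n else ""
        lines.append(f"  {name}: {count}{pct}")
    if report["potentially_eligible_missing_criteria"]:
        lines.append("missing criteria of potentially eligible patients:")
        for pid, missing in report["potentially_eligible_missing_criteria"].items():
            lines.append(f"  {pid}: {', '.join(missing)}")
    if report["not_eligible_causes"]:
        lines.append("causes of rejection:")
        for pid, causes in report["not_eligible_causes"].items():
            parts = []
            if causes["failed_inclusions"]:
                parts.append(
                    "failed inclusion " + ", ".join(causes["failed_inclusions"])
                )
            if causes["matched_exclusions"]:
                parts.append(
                    "matched exclusion " + ", ".join(causes["matched_exclusions"])
                )
            lines.append(f"  {pid}: {'; '.join(parts)}")
    over = report["closed_world_over_rejections"]
    lines.append(
        "patients a closed-world policy would over-reject: "
        + (", ".join(over) if over else "none")
    )
    return "\n".join(lines)


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2)
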