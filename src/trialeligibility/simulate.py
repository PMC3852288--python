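"""Synthetic patient cohorts with controlled missingness.

The generator emulates the structure of pre-screening data collected on
standardized case-report forms: per field, a value is observed with
probability ``p_known`` (a handful of administrative fields are always
filled), and an observed criterion status is true with probability
``p_true``.  Statuses are independent across patients and fields.

The ``mdm-like`` preset mirrors a 65-field multidisciplinary-meeting form
over 286 cases in which 60.90% of all values were unspecified and six
fields were systematically filled: with 6 of 65 fields always known, the
per-field observation probability of the remaining 59 is set so that the
expected overall unknown fraction is 0.609.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PatientRecord, TruthValue, ValidationError

__all__ = [
    "SimulationConfig",
    "mdm_like_config",
    "generate_cohort",
    "generate_field_table",
    "MDM_UNKNOWN_FRACTION",
    "MDM_N_FIELDS",
    "MDM_N_ALWAYS_KNOWN",
    "MDM_N_CASES",
]

# study-condition constants for the mdm-like preset
MDM_UNKNOWN_FRACTION = 0.609
MDM_N_FIELDS = 65
MDM_N_ALWAYS_KNOWN = 6
MDM_N_CASES = 286

GENERATOR_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``p_known`` and ``p_true`` may be a single float (applied to every id)
    or a per-id mapping.  Ids in ``always_known`` are observed with
    probability one regardless of ``p_known``.
    """

    n_patients: int
    ids: tuple[str, ...]
    p_known: float | Mapping[str, float] = 1.0
    p_true: float | Mapping[str, float] = 0.5
    seed: int = 0
    always_known: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be non-negative")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in simulation config")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "always_known", frozenset(self.always_known))
        unknown_ids = self.always_known - set(self.ids)
        if unknown_ids:
            raise ValidationError(
                f"always_known ids not among ids: {sorted(unknown_ids)}"
            )
        for name in ("p_known", "p_true"):
            spec = getattr(self, name)
            probs = spec.values() if isinstance(spec, Mapping) else [spec]
            for p in probs:
                if not 0.0 <= float(p) <= 1.0:
                    raise ValidationError(f"{name} must lie in [0, 1], got {p}")

    def prob_known(self, cid: str) -> float:
        if cid in self.always_known:
            return 1.0
        if isinstance(self.p_known, Mapping):
            return float(self.p_known[cid])
        return float(self.p_known)

    def prob_true(self, cid: str) -> float:
        if isinstance(self.p_true, Mapping):
            return float(self.p_true[cid])
        return float(self.p_true)

    @property
    def algorithm(self) -> str:
        """Name of the pseudo-random generator, for provenance."""
        return GENERATOR_ALGORITHM


def mdm_like_config(
    n_patients: int = MDM_N_CASES, seed: int = 0
) -> SimulationConfig:
    """Preset emulating the multidisciplinary-meeting form's missingness.

    65 fields of which 6 are always known; the observation probability of
    the other 59 is calibrated so the expected unknown fraction over all
    65 columns equals 0.609.
    """
    n_variable = MDM_N_FIELDS - MDM_N_ALWAYS_KNOWN
    # unknown cells arise only in the variable fields:
    # (1 - p) * n_variable / n_fields = MDM_UNKNOWN_FRACTION
    p_known = 1.0 - MDM_UNKNOWN_FRACTION * MDM_N_FIELDS / n_variable
    ids = tuple(f"field_{i:02d}" for i in range(MDM_N_FIELDS))
    return SimulationConfig(
        n_patients=n_patients,
        ids=ids,
        p_known=p_known,
        p_true=0.5,
        seed=seed,
        always_known=frozenset(ids[:MDM_N_ALWAYS_KNOWN]),
    )


def generate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Draw a cohort of three-valued criterion-status records.

    Each status is independently observed with its id's ``p_known``;
    observed statuses are true with ``p_true``.  Unobserved statuses are
    absent from the record (the unknown encoding).  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.ids)
    known_p = np.array([config.prob_known(c) for c in config.ids])
    true_p = np.array([config.prob_true(c) for c in config.ids])
    observed = rng.random((config.n_patients, k)) < known_p
    truths = rng.random((config.n_patients, k)) < true_p
    records = []
    for i in range(config.n_patients):
        statuses = {
            cid: TruthValue.TRUE if truths[i, j] else TruthValue.FALSE
            for j, cid in enumerate(config.ids)
            if observed[i, j]
        }
        records.append(PatientRecord(patient_id=f"sp{i:05d}", statuses=statuses))
    return records


def generate_field_table(
    config: SimulationConfig,
    value_model: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Tabular counterpart of :func:`generate_cohort`.

    ``value_model`` maps a field id to a distribution spec: either
    ``("uniform_int", low, high)`` for uniform integers in [low, high], or
    ``("categorical", {value: weight, ...})``.  Fields without a spec get
    uniform integers in [0, 1].  Missing cells (unobserved) are NaN.
    Returns a DataFrame indexed by patient_id.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    value_model = dict(value_model or {})
    columns: dict[str, np.ndarray] = {}
    for cid in config.ids:
        observed = rng.random(n) < config.prob_known(cid)
        spec = value_model.get(cid, ("uniform_int", 0, 1))
        kind = spec[0]
        if kind == "uniform_int":
            _, low, high = spec
            values = rng.integers(int(low), int(high) + 1, size=n).astype(object)
        elif kind == "categorical":
            _, weights = spec
            cats = list(weights)
            w = np.array([weights[c] for c in cats], dtype=float)
            values = rng.choice(np.array(cats, dtype=object), size=n, p=w / w.sum())
        else:
            raise ValidationError(f"unknown distribution spec {spec!r}")
        values = np.where(observed, values, np.nan)
        columns[cid] = values
    index = pd.Index([f"sp{i:05d}" for i in range(n)], name="patient_id")
    return pd.DataFrame(columns, index=index)
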