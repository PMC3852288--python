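# trialeligibility

Three-valued, open-world determination of clinical-trial eligibility for
patients with partially-known records.

## The problem

During pre-screening — before informed consent, typically in an oncology
multidisciplinary meeting — a patient's record rarely contains everything
needed to decide every eligibility criterion.  A trial is a pair of
criterion lists ⟨(I_i), (E_j)⟩, and classically

    eligible(p) ⇔ (⋀_i I_i(p)) ∧ (⋀_j ¬E_j(p)).

Under negation as failure (the closed-world reading), any criterion that
cannot be *proven* makes the conjunction false, so every patient with a
single unknown value is rejected — even when the missing value, once
obtained, could make them eligible.  Screening data are dominated by such
gaps: on real multidisciplinary-meeting forms, well over half of all field
values can be unspecified.

This package evaluates the conjunction in **strong Kleene three-valued
logic** instead, with each criterion status in {true, false, unknown} and
unknown encoded by *absence* of an assertion.  The outcome distinguishes:

* **eligible** — every inclusion criterion true, every exclusion criterion
  false;
* **not eligible** — at least one inclusion criterion false or one
  exclusion criterion true (the causes are reported);
* **potentially eligible** — nothing disqualifies the patient, but some
  relevant statuses are unknown (the exact missing criteria are reported,
  so they can be sought).

Closed-world inclusion coincides exactly with provable eligibility, so the
patients it additionally rejects are precisely the potentially-eligible
ones — the over-rejection the open-world evaluation avoids.

The same semantics is also compiled to an **OWL 2 design pattern**: per
criterion a class `C` and a defined complement `Not_C ≡ Criterion ⊓ ¬C`;
per trial a defined class `Ct_include ≡ ⊓ I_i ⊓ ⊓ Not_E_j` plus two
defined exclusion-cause classes `⊔ E_j` and `⊔ Not_I_i`; per patient one
individual typed only by what is known.  A built-in entailment classifier
for this propositional fragment (model enumeration over the serialized
axioms) cross-checks the DL classification against the native engine.

## Worked example

`trials.yaml`:

```yaml
trial_id: fictitious
inclusion: [I0, I1]
exclusion: [E0, E1]
```

`statuses.csv` — nine patients covering every true/false/unknown
combination of `I1` and `E1` (`?` = unknown):

```csv
patient_id,I0,I1,E0,E1
p0,T,T,F,T
p1,T,T,F,F
p2,T,T,F,?
p3,T,F,F,T
p4,T,F,F,F
p5,T,F,F,?
p6,T,?,F,T
p7,T,?,F,F
p8,T,?,F,?
```

```sh
trialelig report --trials trials.yaml --patients statuses.csv
```

prints:

```
Trial fictitious: 9 patients screened
  eligible: 1 (11.11%)
  potentially eligible: 3 (33.33%)
  not eligible: 5 (55.56%)
missing criteria of potentially eligible patients:
  p2: E1
  p7: I1
  p8: E1, I1
causes of rejection:
  p0: matched exclusion E1
  p3: failed inclusion I1; matched exclusion E1
  p4: failed inclusion I1
  p5: failed inclusion I1
  p6: matched exclusion E1
patients a closed-world policy would over-reject: p2, p7, p8
```

Only p1 is provably eligible.  A closed-world screening would reject the
other eight; three of those (p2, p7, p8) are merely undetermined, and the
report names exactly which statuses would settle them.

Other commands: `classify` (per-patient TSV/JSON), `export-owl`
(RDF/XML, Turtle or functional syntax), `crosscheck` (engine vs ontology
classification), `bind` (derive statuses from a raw field table via
comparator rules), `simulate` (synthetic cohorts with controlled
missingness, including an `mdm-like` preset: 65 fields, 6 always filled,
calibrated to a 60.9% unknown fraction), and `stats` (missingness report).

The same surface is available as a library:

```python
from trialeligibility import TrialDefinition, PatientRecord, TruthValue, \
    evaluate_open_world

trial = TrialDefinition("fictitious", inclusion=("I0", "I1"),
                        exclusion=("E0", "E1"))
p8 = PatientRecord("p8", {"I0": TruthValue.TRUE, "E0": TruthValue.FALSE})
result = evaluate_open_world(trial, p8)
result.decision.value       # 'potentially eligible'
sorted(result.missing_criteria)  # ['E1', 'I1']
```

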