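# Methods

## Eligibility model

A trial is an ordered pair of duplicate-free criterion-id lists,
inclusion (I_i) and exclusion (E_j); a criterion appearing in both lists
of one trial makes it unsatisfiable and is rejected at validation (the
same criterion may switch roles across trials).  Criteria are assumed
independent: no status is inferred from other statuses, and no propagation
happens between criteria.

Patient knowledge is a partial map from criterion ids to {true, false};
an id absent from the map is *unknown*.  Unknown means absence of
information, never absence of the condition — the open-world reading.

Eligibility is the conjunction (⋀_i I_i) ∧ (⋀_j ¬E_j) evaluated in strong
Kleene logic: negation swaps true/false and fixes unknown; a conjunction
is false if any conjunct is false, otherwise unknown if any conjunct is
unknown, otherwise true (the empty conjunction is true, so a trial with no
criteria accepts everyone).  The three truth values map to the decisions
eligible / not eligible / potentially eligible.  Cause sets are reported
with every decision: false inclusion criteria, true exclusion criteria,
and the unknown criteria on each side.  A not-eligible patient may still
carry unknowns; they are reported (they say what else could not be
verified) but play no role in the decision.

On this propositional fragment the Kleene evaluation coincides exactly
with two independent semantics, and the test suite checks both:

* **Completion semantics.** Enumerate every classical completion of the
  unknown statuses: eligible iff all completions are eligible, not
  eligible iff none is, potentially eligible otherwise.  The
  `completion_oracle` implements this brute force (capped at 20 unknowns,
  2^20 completions) and agrees with the engine exhaustively over every
  trial shape with up to six criteria and every tri-valued status vector.
* **OWL entailment.** See below.

The closed-world baseline (`evaluate_closed_world`) treats a conjunct as
satisfied only when provable: include iff every inclusion criterion is
true *and* every exclusion criterion is false; anything unknown rejects.
We deliberately do not use the naive negation-as-failure reading in which
¬E_j would succeed on an unknown E_j: converting criteria between
inclusion and exclusion form flips what "unprovable" does to them, so that
reading is not a coherent policy — the baseline instead matches the
"cannot assert" interpretation under which every unknown blocks inclusion.
`compare_policies` returns the over-rejection set: patients excluded by
the baseline whose open-world status is potentially eligible.  Since
closed-world inclusion is equivalent to provable eligibility, this set is
exactly the potentially-eligible patients.

## OWL 2 design pattern

For each criterion c the compiler emits a class `C_c` and a defined
complement `Not_C_c ≡ Criterion ⊓ ¬C_c`; for each trial k, five classes:

    Ct_k (placeholder)
    Ct_k_include  ≡  ⊓_i C_I_i  ⊓  ⊓_j Not_C_E_j          ⊑ Ct_k
    Ct_k_exclude (placeholder)                             ⊑ Ct_k
    Ct_k_exclude_at_least_one_exclusion_criterion ≡ ⊔_j C_E_j       ⊑ Ct_k_exclude
    Ct_k_exclude_at_least_one_failed_inclusion_criterion ≡ ⊔_i Not_C_I_i ⊑ Ct_k_exclude

A model with c criteria and t trials declares 1 + 2c + 5t classes.  Each
patient is one named individual, asserted an instance of the `Criterion`
root, of `C_c` for every status known true and `Not_C_c` for every status
known false — and of nothing for an unknown status.  Patients are asserted
directly into criterion classes (no Patient class or property
reification); the root-membership assertion is included so the `Not_C`
equivalence has its left conjunct available, a detail the pattern needs
for the equivalence to classify individuals.  No disjointness axioms are
added beyond what the complement equivalence already entails.  Degenerate
trials serialize as `owl:Thing` (empty intersection) and `owl:Nothing`
(empty union).

Criterion definitions over raw data (necessary-and-sufficient conditions
or rules) are not emitted; statuses are precomputed by the binding module
and asserted as types.

IRIs are `base_iri + "#" + fragment` with prefixes `C_`, `Not_C_`, `Ct_`;
fragments sanitize non-alphanumerics to underscores, so output is
deterministic and diff-stable.  Serializations: RDF/XML (default) and
Turtle via rdflib, plus OWL functional-style syntax emitted (and parsed
back) by the package itself.

### Entailment classification

`classify_with_reasoner` decides inferred class membership of every
patient individual.  The pattern stays inside a propositional fragment of
OWL 2 — every class is a criterion class, its defined complement, or an
intersection/union of those — so entailment is decidable by enumeration:
an individual is an entailed member of a defined class iff the class
expression is true in every model, and the models are exactly the
assignments of true/false to the criterion classes the individual is not
asserted into (the asserted ones are fixed).  The classifier parses the
serialized document (any of the three formats), extracts the axioms,
checks ABox consistency (an individual asserted into both `C` and `Not_C`
is reported with its name), and enumerates (capped at 2^20 per class
check).  It is sound and complete for this fragment; it is not a general
OWL DL reasoner and makes no claim beyond the fragment it parses.

Because the classifier works only on the serialized axioms and never
touches the engine's data structures, `crosscheck_engine_vs_reasoner` is a
genuine dual-route check: inferred membership in `Ct_k_include` maps to
eligible, membership in either exclusion-cause class to not eligible,
neither to potentially eligible, and the mapped decisions are diffed
against the engine per patient and trial.  Agreement is tested
exhaustively on all trial shapes up to four criteria and all 3^4 records
of the four-criterion validation trial, and by seeded sampling on a
six-criterion trial.

## Criterion binding

Raw patient tables are bound to criteria by declarative rules, one rule
per criterion: a field name, a comparator (`eq`, `ne`, `lt`, `le`, `gt`,
`ge`, `in`, `not_in`, `present`, `absent`) and an operand.  Ordering
comparators require numeric operands and numeric cells (a non-numeric cell
is a data error naming the patient, field and value, not a silent
unknown).  Equality is type-faithful: numeric operands compare
numerically, string operands as trimmed strings.  A missing cell — empty,
`NA`, `not specified`, `?` or `unknown`, case-insensitively — yields
unknown, except for `present`/`absent`, which test availability itself and
always decide.  Complex criteria must be decomposed by the user into
atomic rules combined at trial level; there is no unit conversion and no
temporal logic.  Consequently, the unknown statuses among bound criteria
equal the missing cells in the bound columns exactly (missingness
conservation), which the tests assert across the generator–binder
pipeline.

## Synthetic cohorts

The generator draws statuses independently per patient and per id: each
status is observed with probability `p_known` (ids in `always_known` are
always observed), and an observed status is true with probability
`p_true`.  The field-table variant draws cell values from per-field specs
(uniform integers or weighted categories) and blanks unobserved cells.
Randomness comes from `numpy.random.Generator` (PCG64) seeded from the
config, so cohorts are exactly reproducible; the algorithm name is exposed
on the config for provenance.

The `mdm-like` preset emulates the missingness structure of a
65-field multidisciplinary-meeting case-report form over 286 cases with
an overall unknown fraction of 0.609 and six systematically filled
administrative fields: with 6 of 65 fields always known, the remaining 59
are observed with probability 1 − 0.609·65/59 ≈ 0.329, making the expected
overall unknown fraction exactly 0.609.  `p_true` defaults to 0.5 — the
preset reproduces the missingness structure, not clinical value
distributions.

What the generator does *not* emulate: correlated or informative
missingness (real screening data are missing not-at-random — absent
findings often mean "not looked for", which is itself informative),
realistic marginal distributions, and dependencies between criteria.
Passing tests therefore demonstrate the logic and its calibration under
independence, not performance on any real cohort.

## Numerical and design choices

* Unknown is encoded by absence everywhere (record maps, OWL assertions,
  CSV `?` cells normalize to absence on load), so there is exactly one
  representation of ignorance.
* Decision names in rendered reports: "eligible", "not eligible",
  "potentially eligible"; percentages render to two decimals; full
  precision is kept internally.
* "Common fields" in the per-trial field report are fields referenced
  both by a rule bound to an inclusion criterion and by a rule bound to an
  exclusion criterion of the same trial; the report documents this as its
  definition since field overlap can be counted in several ways.
* Enumeration caps: 20 unknowns for the completion oracle and per
  entailment check.  Deterministic tie-breaks: criteria evaluated in list
  order (decisions are order-invariant; tested), sorted cause sets in all
  rendered output.
* Problem sizes in tests and the acceptance script — exhaustive trial
  shapes to six criteria (7,108 vectors), 81 records for the ontology
  cross-check, n = 10,000 for generator calibration — are chosen so each
  property is checked exhaustively where the space is small and by seeded
  sampling where it is not, while the whole suite stays fast enough to run
  on every change.

## Limitations

* The engine decides per-criterion statuses it is given; it does not
  extract criteria from free text, reconcile terminologies, or reason
  about time ("within 6 months of ...").
* The entailment classifier covers exactly the fragment the compiler
  emits; ontologies with constructs outside it are rejected rather than
  classified.
* No probabilistic treatment of unknowns: assuming or imputing statuses
  is out of scope by design — undetermined patients are surfaced with
  their missing criteria instead of being guessed at.
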