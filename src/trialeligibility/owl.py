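"""Compile trials, criteria and patients into an OWL 2 ontology.

The design pattern, per criterion ``c`` and trial ``k``:

* a class ``C_c`` for the certain presence of the criterion and a class
  ``Not_C_c`` defined as ``Not_C_c EquivalentTo Criterion and not C_c``
  for its certain absence;
* a placeholder class ``Ct_k`` with subclasses ``Ct_k_include`` (defined as
  the intersection of all inclusion ``C`` classes and all exclusion
  ``Not_C`` classes) and ``Ct_k_exclude``, the latter with two defined
  subclasses: the union of the exclusion ``C`` classes ("matched at least
  one exclusion criterion") and the union of the inclusion ``Not_C``
  classes ("failed at least one inclusion criterion");
* one named individual per patient, asserted an instance of the
  ``Criterion`` root, of ``C_c`` for every criterion known true and of
  ``Not_C_c`` for every criterion known false — and of nothing for a
  criterion whose status is unknown.  Under the open-world assumption the
  absent assertion carries the "unknown" semantics.

A model with c criteria and t trials declares 1 + 2c + 5t classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdflib import OWL, RDF, RDFS, BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection

from .model import (
    Criterion,
    PatientRecord,
    TrialDefinition,
    TruthValue,
    ValidationError,
    validate_trial,
)

__all__ = [
    "OntologyModel",
    "TrialClassNames",
    "sanitize_fragment",
    "build_ontology",
    "to_graph",
    "serialize_ontology",
]

ROOT_CLASS = "Criterion"

_FRAGMENT_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_fragment(raw: str) -> str:
    """Make an id safe as an IRI fragment: non-alphanumerics become ``_``."""
    frag = re.sub(r"[^A-Za-z0-9_]", "_", raw.strip())
    if not frag or not _FRAGMENT_OK.match(frag):
        raise ValidationError(f"id {raw!r} cannot be sanitized to an IRI fragment")
    return frag


@dataclass(frozen=True)
class TrialClassNames:
    """The five class-name fragments the pattern emits per trial."""

    placeholder: str
    include: str
    exclude: str
    exclude_matched_exclusion: str
    exclude_failed_inclusion: str

    @classmethod
    def for_trial(cls, trial_id: str) -> "TrialClassNames":
        base = f"Ct_{sanitize_fragment(trial_id)}"
        return cls(
            placeholder=base,
            include=f"{base}_include",
            exclude=f"{base}_exclude",
            exclude_matched_exclusion=f"{base}_exclude_at_least_one_exclusion_criterion",
            exclude_failed_inclusion=f"{base}_exclude_at_least_one_failed_inclusion_criterion",
        )


@dataclass(frozen=True)
class OntologyModel:
    """In-memory form of the compiled ontology.

    ``assertions`` holds, per patient individual, the criterion statuses
    that are known (true or false); unknown statuses are deliberately not
    represented — their absence *is* the open-world encoding.
    """

    base_iri: str
    criteria: tuple[str, ...]
    trials: tuple[TrialDefinition, ...]
    assertions: tuple[tuple[str, tuple[tuple[str, bool], ...]], ...] = ()

    @property
    def criterion_classes(self) -> dict[str, tuple[str, str]]:
        return {
            c: (f"C_{sanitize_fragment(c)}", f"Not_C_{sanitize_fragment(c)}")
            for c in self.criteria
        }

    @property
    def trial_classes(self) -> dict[str, TrialClassNames]:
        return {t.trial_id: TrialClassNames.for_trial(t.trial_id) for t in self.trials}

    @property
    def class_names(self) -> list[str]:
        names = [ROOT_CLASS]
        for c, notc in self.criterion_classes.values():
            names.extend((c, notc))
        for tc in self.trial_classes.values():
            names.extend(
                (
                    tc.placeholder,
                    tc.include,
                    tc.exclude,
                    tc.exclude_matched_exclusion,
                    tc.exclude_failed_inclusion,
                )
            )
        return names


def build_ontology(
    trials: Sequence[TrialDefinition],
    registry: Iterable[Criterion],
    patients: Sequence[PatientRecord],
    base_iri: str = "http://example.org/eligibility",
) -> OntologyModel:
    """Compile validated trials, a criterion registry and patient records.

    Every criterion in the registry gets its class pair whether or not a
    trial references it; patients contribute one individual each, typed by
    the classes of their known statuses only.
    """
    registry = list(registry)
    criteria = tuple(c.id for c in registry)
    if len(set(criteria)) != len(criteria):
        raise ValidationError("duplicate criterion ids in registry")
    for t in trials:
        validate_trial(t, registry)
    assertions = []
    for p in patients:
        p.check_registry(registry)
        known = tuple(
            (cid, v is TruthValue.TRUE)
            for cid, v in sorted(p.statuses.items())
            if v is not TruthValue.UNKNOWN
        )
        assertions.append((p.patient_id, known))
    return OntologyModel(
        base_iri=base_iri.rstrip("#/"),
        criteria=criteria,
        trials=tuple(trials),
        assertions=tuple(assertions),
    )


def _class_list(graph: Graph, members: Sequence[URIRef]) -> BNode:
    node = BNode()
    Collection(graph, node, list(members))
    return node


def _intersection_of(graph: Graph, members: Sequence[URIRef]) -> URIRef | BNode:
    if not members:
        return OWL.Thing  # empty conjunction
    if len(members) == 1:
        return members[0]
    node = BNode()
    graph.add((node, RDF.type, OWL.Class))
    graph.add((node, OWL.intersectionOf, _class_list(graph, members)))
    return node


def _union_of(graph: Graph, members: Sequence[URIRef]) -> URIRef | BNode:
    if not members:
        return OWL.Nothing  # empty disjunction
    if len(members) == 1:
        return members[0]
    node = BNode()
    graph.add((node, RDF.type, OWL.Class))
    graph.add((node, OWL.unionOf, _class_list(graph, members)))
    return node


def to_graph(model: OntologyModel) -> Graph:
    """Realize the model as an rdflib graph of OWL 2 axioms."""
    ns = Namespace(model.base_iri + "#")
    g = Graph()
    g.bind("owl", OWL)
    g.bind("", ns)
    ontology = URIRef(model.base_iri)
    g.add((ontology, RDF.type, OWL.Ontology))

    def cls(name: str) -> URIRef:
        return ns[name]

    for name in model.class_names:
        g.add((cls(name), RDF.type, OWL.Class))

    root = cls(ROOT_CLASS)
    crit = model.criterion_classes
    for cid, (c_name, notc_name) in crit.items():
        # Not_C  EquivalentTo  Criterion and (not C)
        comp = BNode()
        g.add((comp, RDF.type, OWL.Class))
        g.add((comp, OWL.complementOf, cls(c_name)))
        inter = BNode()
        g.add((inter, RDF.type, OWL.Class))
        g.add((inter, OWL.intersectionOf, _class_list(g, [root, comp])))
        g.add((cls(notc_name), OWL.equivalentClass, inter))

    for trial in model.trials:
        tc = TrialClassNames.for_trial(trial.trial_id)
        g.add((cls(tc.include), RDFS.subClassOf, cls(tc.placeholder)))
        g.add((cls(tc.exclude), RDFS.subClassOf, cls(tc.placeholder)))
        g.add((cls(tc.exclude_matched_exclusion), RDFS.subClassOf, cls(tc.exclude)))
        g.add((cls(tc.exclude_failed_inclusion), RDFS.subClassOf, cls(tc.exclude)))

        inc_c = [cls(crit[c][0]) for c in trial.inclusion]
        exc_c = [cls(crit[c][0]) for c in trial.exclusion]
        exc_not = [cls(crit[c][1]) for c in trial.exclusion]
        inc_not = [cls(crit[c][1]) for c in trial.inclusion]

        g.add((cls(tc.include), OWL.equivalentClass, _intersection_of(g, inc_c + exc_not)))
        g.add((cls(tc.exclude_matched_exclusion), OWL.equivalentClass, _union_of(g, exc_c)))
        g.add((cls(tc.exclude_failed_inclusion), OWL.equivalentClass, _union_of(g, inc_not)))

    for patient_id, known in model.assertions:
        ind = ns[sanitize_fragment(patient_id)]
        g.add((ind, RDF.type, OWL.NamedIndividual))
        g.add((ind, RDF.type, root))
        for cid, value in known:
            c_name, notc_name = crit[cid]
            g.add((ind, RDF.type, cls(c_name if value else notc_name)))
    return g


# ---------------------------------------------------------------------------
# OWL 2 functional-style syntax

def _ofn_expr(members: list[str], op: str) -> str:
    if not members:
        return "owl:Thing" if op == "ObjectIntersectionOf" else "owl:Nothing"
    if len(members) == 1:
        return members[0]
    return f"{op}( {' '.join(members)} )"


def _to_functional(model: OntologyModel) -> str:
    ns = model.base_iri + "#"
    lines = [
        "Prefix(:=<%s>)" % ns,
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        f"Ontology(<{model.base_iri}>",
    ]
    for name in model.class_names:
        lines.append(f"Declaration( Class( :{name} ) )")
    crit = model.criterion_classes
    for c_name, notc_name in crit.values():
        lines.append(
            f"EquivalentClasses( :{notc_name} ObjectIntersectionOf( :{ROOT_CLASS} "
            f"ObjectComplementOf( :{c_name} ) ) )"
        )
    for trial in model.trials:
        tc = TrialClassNames.for_trial(trial.trial_id)
        lines.append(f"SubClassOf( :{tc.include} :{tc.placeholder} )")
        lines.append(f"SubClassOf( :{tc.exclude} :{tc.placeholder} )")
        lines.append(f"SubClassOf( :{tc.exclude_matched_exclusion} :{tc.exclude} )")
        lines.append(f"SubClassOf( :{tc.exclude_failed_inclusion} :{tc.exclude} )")
        inc_c = [f":{crit[c][0]}" for c in trial.inclusion]
        exc_c = [f":{crit[c][0]}" for c in trial.exclusion]
        exc_not = [f":{crit[c][1]}" for c in trial.exclusion]
        inc_not = [f":{crit[c][1]}" for c in trial.inclusion]
        lines.append(
            f"EquivalentClasses( :{tc.include} "
            f"{_ofn_expr(inc_c + exc_not, 'ObjectIntersectionOf')} )"
        )
        lines.append(
            f"EquivalentClasses( :{tc.exclude_matched_exclusion} "
            f"{_ofn_expr(exc_c, 'ObjectUnionOf')} )"
        )
        lines.append(
            f"EquivalentClasses( :{tc.exclude_failed_inclusion} "
            f"{_ofn_expr(inc_not, 'ObjectUnionOf')} )"
        )
    for patient_id, known in model.assertions:
        ind = sanitize_fragment(patient_id)
        lines.append(f"Declaration( NamedIndividual( :{ind} ) )")
        lines.append(f"ClassAssertion( :{ROOT_CLASS} :{ind} )")
        for cid, value in known:
            c_name, notc_name = crit[cid]
            lines.append(f"ClassAssertion( :{c_name if value else notc_name} :{ind} )")
    lines.append(")")
    return "\n".join(lines) + "\n"


_FORMATS = {
    "rdfxml": "xml",
    "rdf/xml": "xml",
    "xml": "xml",
    "turtle": "turtle",
    "ttl": "turtle",
    "ofn": None,
    "functional": None,
}


def serialize_ontology(model: OntologyModel, format: str = "rdfxml") -> str:
    """Serialize to RDF/XML (default), Turtle, or functional-style syntax."""
    key = format.strip().lower()
    if key not in _FORMATS:
        raise ValueError(
            f"unsupported serialization format {format!r}; "
            f"expected one of rdfxml, turtle, ofn"
        )
    if _FORMATS[key] is None:
        return _to_functional(model)
    return to_graph(model).serialize(format=_FORMATS[key])
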