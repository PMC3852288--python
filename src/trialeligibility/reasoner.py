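"""Instance classification of the compiled ontologies by logical entailment.

The design pattern lives in a propositional fragment of OWL 2: every class
is either a criterion class ``C``, its defined complement
``Not_C = Criterion and not C``, or a trial class defined as an
intersection or union of those.  For this fragment, entailed instance
membership can be decided exactly: an individual is an inferred member of a
defined class iff the class expression evaluates to true in *every* model
of the ontology, and the models are precisely the assignments of
true/false to the criterion classes the individual is not asserted into.
``classify_with_reasoner`` implements that decision procedure by
enumeration — a sound and complete OWL 2 entailment check for the
fragment, operating only on the serialized axioms (never on the trial and
patient objects), so it is an independent cross-check of the three-valued
engine.

``crosscheck_engine_vs_reasoner`` compiles, serializes, classifies, maps
the inferred memberships back to eligibility decisions, and diffs them
against the engine patient by patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdflib import OWL, RDF, RDFS, BNode, Graph, URIRef
from rdflib.collection import Collection

from .engine import evaluate_open_world
from .model import (
    Criterion,
    Decision,
    PatientRecord,
    TrialDefinition,
    ValidationError,
)
from .owl import TrialClassNames, build_ontology, serialize_ontology

__all__ = [
    "InconsistentOntologyError",
    "ParsedOntology",
    "ReasonerClassification",
    "Deviation",
    "parse_ontology",
    "classify_with_reasoner",
    "crosscheck_engine_vs_reasoner",
]

_THING = "owl:Thing"
_NOTHING = "owl:Nothing"
_MAX_UNKNOWNS = 20


class InconsistentOntologyError(ValueError):
    """The ABox is unsatisfiable (an individual asserted into C and Not_C)."""


@dataclass
class _Defined:
    """A named class with an equivalence to an intersection/union/atom."""

    name: str
    kind: str  # "intersection" | "union" | "atom"
    operands: tuple[str, ...]


@dataclass
class ParsedOntology:
    """Normalized axioms extracted from a serialized document."""

    root: str | None
    notc_for: dict[str, str]  # positive class -> its defined complement class
    defined: dict[str, _Defined]
    parents: dict[str, set[str]]
    individuals: dict[str, set[str]]  # individual -> asserted named classes
    classes: set[str] = field(default_factory=set)

    @property
    def positive_for(self) -> dict[str, str]:
        return {v: k for k, v in self.notc_for.items()}


def _local(term: URIRef) -> str:
    text = str(term)
    for sep in ("#", "/"):
        if sep in text:
            return text.rsplit(sep, 1)[1]
    return text


def _parse_graph(g: Graph) -> ParsedOntology:
    named_classes = {
        s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)
    }
    po = ParsedOntology(
        root=None,
        notc_for={},
        defined={},
        parents={},
        individuals={},
        classes={_local(c) for c in named_classes},
    )

    def members_of(node: BNode, prop) -> list:
        head = g.value(node, prop)
        return list(Collection(g, head)) if head is not None else []

    for s, o in g.subject_objects(OWL.equivalentClass):
        if not isinstance(s, URIRef):
            continue
        name = _local(s)
        if isinstance(o, URIRef):
            if o == OWL.Thing:
                po.defined[name] = _Defined(name, "atom", (_THING,))
            elif o == OWL.Nothing:
                po.defined[name] = _Defined(name, "atom", (_NOTHING,))
            else:
                po.defined[name] = _Defined(name, "atom", (_local(o),))
            continue
        inter = members_of(o, OWL.intersectionOf)
        union = members_of(o, OWL.unionOf)
        if inter:
            complements = [
                m for m in inter if isinstance(m, BNode)
                and g.value(m, OWL.complementOf) is not None
            ]
            plain = [m for m in inter if isinstance(m, URIRef)]
            if complements:
                # Not_C EquivalentTo Criterion and (not C)
                if len(complements) != 1 or len(plain) != 1:
                    raise ValidationError(
                        f"unsupported complement axiom on class {name!r}"
                    )
                target = g.value(complements[0], OWL.complementOf)
                po.notc_for[_local(target)] = name
                po.root = _local(plain[0])
            else:
                po.defined[name] = _Defined(
                    name, "intersection", tuple(_local(m) for m in inter)
                )
        elif union:
            po.defined[name] = _Defined(
                name, "union", tuple(_local(m) for m in union)
            )
        else:
            raise ValidationError(f"unsupported class expression for {name!r}")

    for s, o in g.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            po.parents.setdefault(_local(s), set()).add(_local(o))

    for s, o in g.subject_objects(RDF.type):
        if not isinstance(s, URIRef) or not isinstance(o, URIRef):
            continue
        if o in (OWL.Class, OWL.Ontology, OWL.NamedIndividual):
            if o == OWL.NamedIndividual:
                po.individuals.setdefault(_local(s), set())
            continue
        if o in named_classes:
            po.individuals.setdefault(_local(s), set()).add(_local(o))
    return po


# -- functional-style syntax ------------------------------------------------

def _tokenize_ofn(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def _parse_ofn(text: str) -> ParsedOntology:
    tokens = _tokenize_ofn(text)
    pos = 0

    def peek() -> str:
        return tokens[pos]

    def take(expected: str | None = None) -> str:
        nonlocal pos
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValidationError(f"functional-syntax parse error near {tok!r}")
        pos += 1
        return tok

    def name(tok: str) -> str:
        return tok[1:] if tok.startswith(":") else tok

    def parse_expr() -> tuple[str, tuple[str, ...]]:
        tok = take()
        if tok in ("ObjectIntersectionOf", "ObjectUnionOf", "ObjectComplementOf"):
            take("(")
            members: list[tuple[str, tuple[str, ...]]] = []
            while peek() != ")":
                members.append(parse_expr())
            take(")")
            kind = {
                "ObjectIntersectionOf": "intersection",
                "ObjectUnionOf": "union",
                "ObjectComplementOf": "complement",
            }[tok]
            flat: list[str] = []
            for k, ops in members:
                if k == "atom":
                    flat.extend(ops)
                elif k == "complement" and kind == "intersection":
                    flat.append("~" + ops[0])
                else:
                    raise ValidationError("unsupported nested class expression")
            return kind, tuple(flat)
        return "atom", (name(tok),)

    po = ParsedOntology(
        root=None, notc_for={}, defined={}, parents={}, individuals={}
    )
    while pos < len(tokens):
        tok = take()
        if tok == "Declaration":
            take("(")
            what = take()
            take("(")
            ident = name(take())
            take(")")
            take(")")
            if what == "Class":
                po.classes.add(ident)
            elif what == "NamedIndividual":
                po.individuals.setdefault(ident, set())
        elif tok == "SubClassOf":
            take("(")
            child, parent = name(take()), name(take())
            take(")")
            po.parents.setdefault(child, set()).add(parent)
        elif tok == "ClassAssertion":
            take("(")
            cls_name, ind = name(take()), name(take())
            take(")")
            po.individuals.setdefault(ind, set()).add(cls_name)
        elif tok == "EquivalentClasses":
            take("(")
            lhs = name(take())
            kind, ops = parse_expr()
            take(")")
            complements = [o for o in ops if o.startswith("~")]
            if kind == "intersection" and complements:
                if len(complements) != 1 or len(ops) != 2:
                    raise ValidationError(
                        f"unsupported complement axiom on class {lhs!r}"
                    )
                plain = next(o for o in ops if not o.startswith("~"))
                po.notc_for[complements[0][1:]] = lhs
                po.root = plain
            else:
                po.defined[lhs] = _Defined(lhs, kind, ops)
    return po


def parse_ontology(document: str, format: str = "rdfxml") -> ParsedOntology:
    """Parse a serialized ontology into its normalized axioms."""
    key = format.strip().lower()
    if key in ("ofn", "functional"):
        return _parse_ofn(document)
    if key in ("rdfxml", "rdf/xml", "xml"):
        rdflib_fmt = "xml"
    elif key in ("turtle", "ttl"):
        rdflib_fmt = "turtle"
    else:
        raise ValueError(f"unsupported format {format!r}")
    g = Graph()
    g.parse(data=document, format=rdflib_fmt)
    return _parse_graph(g)


# -- entailment -------------------------------------------------------------

@dataclass(frozen=True)
class ReasonerClassification:
    """Inferred trial-class memberships per patient individual.

    ``memberships`` maps individual -> defined-class name -> bool (entailed
    membership).  ``decisions`` maps individual -> trial placeholder class
    -> eligibility decision, using the pattern's reading: member of the
    include class = eligible, member of an exclude class = not eligible,
    neither = undetermined.
    """

    memberships: Mapping[str, Mapping[str, bool]]
    decisions: Mapping[str, Mapping[str, Decision]]


def _known_statuses(
    po: ParsedOntology, asserted: set[str]
) -> dict[str, bool]:
    known: dict[str, bool] = {}
    for positive, notc in po.notc_for.items():
        has_pos = positive in asserted
        has_neg = notc in asserted
        if has_pos and has_neg:
            raise InconsistentOntologyError(
                f"individual asserted both {positive!r} and {notc!r}"
            )
        if has_pos:
            known[positive] = True
        elif has_neg:
            known[positive] = False
    return known


def _entailed(
    po: ParsedOntology, defined: _Defined, known: dict[str, bool]
) -> bool:
    """Membership in every model of the ontology, by enumeration."""
    positive_for = po.positive_for

    def base_of(operand: str) -> str | None:
        if operand in positive_for:
            return positive_for[operand]
        if operand in po.notc_for:
            return operand
        return None

    relevant = sorted(
        {b for op in defined.operands if (b := base_of(op)) is not None}
    )
    free = [b for b in relevant if b not in known]
    if len(free) > _MAX_UNKNOWNS:
        raise ValidationError(
            f"entailment check limited to {_MAX_UNKNOWNS} unasserted criteria"
        )

    def value(operand: str, model: dict[str, bool]) -> bool:
        if operand == _THING or operand == po.root:
            return True
        if operand == _NOTHING:
            return False
        if operand in positive_for:
            return not model[positive_for[operand]]
        if operand in po.notc_for:
            return model[operand]
        raise ValidationError(f"operand {operand!r} is not a criterion class")

    for bits in range(1 << len(free)):
        model = dict(known)
        for i, b in enumerate(free):
            model[b] = bool((bits >> i) & 1)
        vals = (value(op, model) for op in defined.operands)
        if defined.kind in ("intersection", "atom"):
            holds = all(vals)
        else:
            holds = any(vals)
        if not holds:
            return False
    return True


def _trial_groups(po: ParsedOntology) -> dict[str, dict[str, str]]:
    """Group defined classes by trial placeholder via the subclass wiring.

    Returns placeholder -> {"include": name, "exclude_matched_exclusion":
    name, "exclude_failed_inclusion": name}.
    """
    groups: dict[str, dict[str, str]] = {}
    for d in po.defined.values():
        supers = po.parents.get(d.name, set())
        if not supers:
            continue
        parent = next(iter(supers))
        grandparents = po.parents.get(parent, set())
        if grandparents:
            # a reason class: parent is the exclude placeholder
            placeholder = next(iter(grandparents))
            operands_not = [op for op in d.operands if op in po.positive_for]
            role = (
                "exclude_failed_inclusion"
                if operands_not
                else "exclude_matched_exclusion"
            )
            if all(op in (_NOTHING,) for op in d.operands):
                # empty union: role is immaterial, keep both slots filled
                slot = groups.setdefault(placeholder, {})
                role = (
                    "exclude_matched_exclusion"
                    if "exclude_matched_exclusion" not in slot
                    else "exclude_failed_inclusion"
                )
            groups.setdefault(placeholder, {})[role] = d.name
        else:
            groups.setdefault(parent, {})["include"] = d.name
    return groups


def classify_with_reasoner(
    document: str, format: str = "rdfxml"
) -> ReasonerClassification:
    """Classify every patient individual in a serialized ontology.

    Verifies ABox consistency first, then decides entailed membership of
    each individual in each trial's include and exclude-reason classes and
    maps the memberships to eligibility decisions per trial.
    """
    po = parse_ontology(document, format=format)
    groups = _trial_groups(po)
    memberships: dict[str, dict[str, bool]] = {}
    decisions: dict[str, dict[str, Decision]] = {}
    for ind, asserted in sorted(po.individuals.items()):
        known = _known_statuses(po, asserted)
        memberships[ind] = {}
        decisions[ind] = {}
        for placeholder, roles in groups.items():
            inferred: dict[str, bool] = {}
            for role, cls_name in roles.items():
                inferred[cls_name] = _entailed(po, po.defined[cls_name], known)
                memberships[ind][cls_name] = inferred[cls_name]
            include_cls = roles.get("include")
            in_include = bool(include_cls) and inferred.get(include_cls, False)
            in_exclude = any(
                inferred.get(roles[r], False)
                for r in ("exclude_matched_exclusion", "exclude_failed_inclusion")
                if r in roles
            )
            if in_include and in_exclude:  # pragma: no cover - unsatisfiable
                raise InconsistentOntologyError(
                    f"individual {ind!r} inferred both eligible and excluded "
                    f"for {placeholder!r}"
                )
            if in_include:
                decisions[ind][placeholder] = Decision.ELIGIBLE
            elif in_exclude:
                decisions[ind][placeholder] = Decision.NOT_ELIGIBLE
            else:
                decisions[ind][placeholder] = Decision.UNDETERMINED
    return ReasonerClassification(memberships=memberships, decisions=decisions)


@dataclass(frozen=True)
class Deviation:
    """A disagreement between the engine and the ontology classification."""

    patient_id: str
    trial_id: str
    engine_decision: Decision
    reasoner_decision: Decision


def crosscheck_engine_vs_reasoner(
    trials: Sequence[TrialDefinition],
    registry: Iterable[Criterion],
    patients: Sequence[PatientRecord],
    base_iri: str = "http://example.org/eligibility",
    format: str = "rdfxml",
) -> list[Deviation]:
    """Compile, serialize, classify, and diff against the native engine.

    Returns the empty list when the ontology classification agrees with
    the three-valued engine for every patient and every trial.
    """
    registry = list(registry)
    model = build_ontology(trials, registry, patients, base_iri=base_iri)
    document = serialize_ontology(model, format=format)
    classification = classify_with_reasoner(document, format=format)
    deviations: list[Deviation] = []
    for trial in trials:
        placeholder = TrialClassNames.for_trial(trial.trial_id).placeholder
        for p in patients:
            engine = evaluate_open_world(trial, p).decision
            inferred = classification.decisions[p.patient_id][placeholder]
            if engine is not inferred:
                deviations.append(
                    Deviation(
                        patient_id=p.patient_id,
                        trial_id=trial.trial_id,
                        engine_decision=engine,
                        reasoner_decision=inferred,
                    )
                )
    return deviations
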