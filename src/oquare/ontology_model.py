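"""Structural view of one OWL ontology version.

An :class:`OntologyGraph` is a uniform, purely structural summary of a single
ontology file: the named classes, the asserted is-a (subClassOf) DAG, the
declared properties, and per-class counts of annotation assertions,
restriction expressions, property usages and individuals.  It is the input of
the metric calculations and of the version-activity diff.

Conventions
-----------
* The root ``owl:Thing`` is implicit: it never appears in ``classes`` but may
  appear as the parent of a subclass edge.  On construction, every class
  without a named parent receives an explicit edge to the root, so the DAG is
  always connected through the root.
* A *property usage* is one occurrence of an object or data property inside a
  class-expression axiom (restrictions on the right-hand side of
  ``subClassOf`` / ``equivalentClass``) or one property assertion on an
  individual.  Property declarations and domain/range axioms are not usages.
* The subclass relation restricted to named classes must be acyclic; a cycle
  is a hard error because the path-based metrics are undefined on cyclic
  graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import rdflib
from rdflib import OWL, RDF, RDFS, BNode, Literal, URIRef

from .errors import OntologyParseError, StructuralError

#: IRI of the implicit root.  Never a member of ``OntologyGraph.classes``.
ROOT = str(OWL.Thing)

# Annotation predicates recognised even without an explicit
# owl:AnnotationProperty declaration.
_BUILTIN_ANNOTATION_PREDICATES = {
    str(RDFS.label),
    str(RDFS.comment),
    str(RDFS.seeAlso),
    str(RDFS.isDefinedBy),
    "http://www.w3.org/2004/02/skos/core#prefLabel",
    "http://www.w3.org/2004/02/skos/core#definition",
    "http://purl.org/dc/elements/1.1/description",
}

#: Default deprecation conventions: the OWL vocabulary flag plus the
#: oboInOwl-style marker used by several OBO Foundry exports.
DEFAULT_DEPRECATION_PREDICATES = (
    str(OWL.deprecated),
    "http://www.geneontology.org/formats/oboInOwl#is_obsolete",
)

#: Labels with this prefix flag the class as obsolete (EDAM convention).
OBSOLETE_LABEL_PREFIX = "OBSOLETE"


def _clean_counts(d: Mapping[str, int]) -> dict[str, int]:
    """Canonical count mapping: drop zero entries, validate non-negativity."""
    out = {}
    for k, v in d.items():
        if v < 0:
            raise ValueError(f"negative count for {k!r}: {v}")
        if v:
            out[k] = int(v)
    return out


def _clean_nested(d: Mapping[str, Mapping[str, int]]) -> dict[str, dict[str, int]]:
    out = {}
    for k, inner in d.items():
        cleaned = _clean_counts(inner)
        if cleaned:
            out[k] = cleaned
    return out


@dataclass
class OntologyGraph:
    """Parsed, normalisable structural view of one OWL version."""

    classes: set[str] = field(default_factory=set)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    data_properties: set[str] = field(default_factory=set)
    #: per class: property -> number of usages inside its class-expression axioms
    class_usages: dict[str, dict[str, int]] = field(default_factory=dict)
    #: per class: property -> number of assertions on individuals of the class
    assertion_usages: dict[str, dict[str, int]] = field(default_factory=dict)
    #: per class: number of annotation assertions
    annotations: dict[str, int] = field(default_factory=dict)
    #: per class: number of asserted individuals
    individuals: dict[str, int] = field(default_factory=dict)
    #: per class: number of restriction expressions in its axioms
    class_restrictions: dict[str, int] = field(default_factory=dict)
    deprecated: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.classes = set(self.classes)
        if ROOT in self.classes:
            raise StructuralError("the implicit root cannot be a declared class")
        self.subclass_edges = set(self.subclass_edges)
        self.object_properties = set(self.object_properties)
        self.data_properties = set(self.data_properties)
        self.class_usages = _clean_nested(self.class_usages)
        self.assertion_usages = _clean_nested(self.assertion_usages)
        self.annotations = _clean_counts(self.annotations)
        self.individuals = _clean_counts(self.individuals)
        self.class_restrictions = _clean_counts(self.class_restrictions)
        self.deprecated = set(self.deprecated)
        # connect parentless classes to the implicit root
        with_parent = {c for c, _ in self.subclass_edges}
        for c in self.classes - with_parent:
            self.subclass_edges.add((c, ROOT))
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        for child, parent in self.subclass_edges:
            if child not in self.classes:
                raise StructuralError(f"subclass edge from undeclared class {child!r}")
            if parent != ROOT and parent not in self.classes:
                raise StructuralError(f"subclass edge to undeclared class {parent!r}")
        for c in self.deprecated:
            if c not in self.classes:
                raise StructuralError(f"deprecated flag on undeclared class {c!r}")
        dag = nx.DiGraph(self.named_edges)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = [u for u, _ in nx.find_cycle(dag)]
            raise StructuralError(
                f"subclass cycle among named classes: {' -> '.join(cycle)}",
                cycle=cycle,
            )

    # -- derived views -----------------------------------------------------

    @property
    def named_edges(self) -> set[tuple[str, str]]:
        """Subclass edges between two named classes (the root excluded)."""
        return {(c, p) for c, p in self.subclass_edges if p != ROOT}

    @property
    def property_usages(self) -> dict[str, int]:
        """Total usages per property, across class axioms and assertions."""
        total: Counter[str] = Counter()
        for usages in self.class_usages.values():
            total.update(usages)
        for usages in self.assertion_usages.values():
            total.update(usages)
        return dict(total)

    @property
    def total_usages(self) -> int:
        return sum(self.property_usages.values())

    @property
    def restrictions(self) -> int:
        """Total count of restriction expressions in class axioms."""
        return sum(self.class_restrictions.values())

    def parents(self, cls: str) -> set[str]:
        return {p for c, p in self.subclass_edges if c == cls}

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {c: set() for c in self.classes}
        for c, p in self.named_edges:
            kids[p].add(c)
        return kids

    @property
    def leaves(self) -> set[str]:
        parents_of_someone = {p for _, p in self.named_edges}
        return self.classes - parents_of_someone

    @property
    def root_children(self) -> set[str]:
        return {c for c, p in self.subclass_edges if p == ROOT}

    # -- equality ----------------------------------------------------------

    def __eq__(self, other):
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.subclass_edges == other.subclass_edges
            and self.object_properties == other.object_properties
            and self.data_properties == other.data_properties
            and self.class_usages == other.class_usages
            and self.assertion_usages == other.assertion_usages
            and self.annotations == other.annotations
            and self.individuals == other.individuals
            and self.class_restrictions == other.class_restrictions
            and self.deprecated == other.deprecated
        )

    def copy(self) -> "OntologyGraph":
        return OntologyGraph(
            classes=set(self.classes),
            subclass_edges=set(self.subclass_edges),
            object_properties=set(self.object_properties),
            data_properties=set(self.data_properties),
            class_usages={c: dict(u) for c, u in self.class_usages.items()},
            assertion_usages={c: dict(u) for c, u in self.assertion_usages.items()},
            annotations=dict(self.annotations),
            individuals=dict(self.individuals),
            class_restrictions=dict(self.class_restrictions),
            deprecated=set(self.deprecated),
        )

    def fingerprint(self, cls: str) -> tuple:
        """Local axiom/annotation fingerprint of one class.

        Covers everything asserted *about* the class: its direct parents, its
        annotation count, its restriction expressions and property usages,
        its individuals and their property assertions, and its deprecation
        flag.  Edges from its children belong to the children.
        """
        return (
            tuple(sorted(self.parents(cls))),
            self.annotations.get(cls, 0),
            self.class_restrictions.get(cls, 0),
            tuple(sorted(self.class_usages.get(cls, {}).items())),
            self.individuals.get(cls, 0),
            tuple(sorted(self.assertion_usages.get(cls, {}).items())),
            cls in self.deprecated,
        )


@dataclass(frozen=True)
class ActivityDelta:
    """Per-version-pair editorial activity: added / deleted / modified classes."""

    n_new: int
    n_deleted: int
    n_changed: int

    def __post_init__(self):
        if min(self.n_new, self.n_deleted, self.n_changed) < 0:
            raise ValueError("activity counts must be non-negative")


# ---------------------------------------------------------------------------
# reading

_RDFLIB_FORMAT = {"rdfxml": "xml", "turtle": "turtle"}


def _guess_dialect(source: str | Path) -> str:
    suffix = Path(source).suffix.lower()
    return "turtle" if suffix in {".ttl", ".n3"} else "rdfxml"


def _walk_expression(rdf: rdflib.Graph, node) -> tuple[int, Counter]:
    """Count restriction expressions and property usages below a class
    expression node (recursing through boolean combinations and fillers)."""
    n_restr = 0
    usages: Counter[str] = Counter()
    if not isinstance(node, BNode):
        return 0, usages
    on_props = list(rdf.objects(node, OWL.onProperty))
    if on_props:
        n_restr += 1
        for p in on_props:
            usages[str(p)] += 1
        for pred in (OWL.someValuesFrom, OWL.allValuesFrom, OWL.hasValue, OWL.onClass):
            for filler in rdf.objects(node, pred):
                nr, us = _walk_expression(rdf, filler)
                n_restr += nr
                usages.update(us)
    for pred in (OWL.intersectionOf, OWL.unionOf):
        for lst in rdf.objects(node, pred):
            for member in rdf.items(lst):
                nr, us = _walk_expression(rdf, member)
                n_restr += nr
                usages.update(us)
    for comp in rdf.objects(node, OWL.complementOf):
        nr, us = _walk_expression(rdf, comp)
        n_restr += nr
        usages.update(us)
    return n_restr, usages


def read_ontology(
    source: str | Path,
    dialect: str = "auto",
    deprecation_predicates: Iterable[str] = DEFAULT_DEPRECATION_PREDICATES,
) -> OntologyGraph:
    """Parse an OWL file (RDF/XML or Turtle) into an :class:`OntologyGraph`.

    Anonymous class expressions are never added to ``classes``; their
    restriction expressions increment the restriction and usage counters of
    the named class whose axiom contains them.
    """
    if dialect == "auto":
        dialect = _guess_dialect(source)
    if dialect not in _RDFLIB_FORMAT:
        raise ValueError(f"unknown dialect {dialect!r}")
    rdf = rdflib.Graph()
    try:
        rdf.parse(str(source), format=_RDFLIB_FORMAT[dialect])
    except Exception as exc:  # rdflib raises many parser-specific types
        raise OntologyParseError(str(source), dialect, str(exc)) from exc
    return graph_from_rdflib(rdf, deprecation_predicates=deprecation_predicates)


def graph_from_rdflib(
    rdf: rdflib.Graph,
    deprecation_predicates: Iterable[str] = DEFAULT_DEPRECATION_PREDICATES,
) -> OntologyGraph:
    deprecation_predicates = set(deprecation_predicates)

    classes = {str(s) for s in rdf.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    # hand-written files often omit declarations for subClassOf endpoints
    for s, o in rdf.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef):
            classes.add(str(s))
        if isinstance(o, URIRef):
            classes.add(str(o))
    classes.discard(ROOT)

    object_properties = {
        str(s) for s in rdf.subjects(RDF.type, OWL.ObjectProperty) if isinstance(s, URIRef)
    }
    data_properties = {
        str(s) for s in rdf.subjects(RDF.type, OWL.DatatypeProperty) if isinstance(s, URIRef)
    }
    declared_annotation = {
        str(s) for s in rdf.subjects(RDF.type, OWL.AnnotationProperty) if isinstance(s, URIRef)
    }
    annotation_predicates = (
        _BUILTIN_ANNOTATION_PREDICATES | declared_annotation
    ) - deprecation_predicates

    subclass_edges: set[tuple[str, str]] = set()
    class_usages: dict[str, dict[str, int]] = {}
    class_restrictions: dict[str, int] = {}
    annotations: dict[str, int] = {}
    deprecated: set[str] = set()

    for c in classes:
        subj = URIRef(c)
        for o in rdf.objects(subj, RDFS.subClassOf):
            if isinstance(o, URIRef):
                subclass_edges.add((c, ROOT if str(o) == ROOT else str(o)))
            else:
                nr, us = _walk_expression(rdf, o)
                if nr:
                    class_restrictions[c] = class_restrictions.get(c, 0) + nr
                    cu = class_usages.setdefault(c, {})
                    for p, k in us.items():
                        cu[p] = cu.get(p, 0) + k
        for o in rdf.objects(subj, OWL.equivalentClass):
            nr, us = _walk_expression(rdf, o)
            if nr:
                class_restrictions[c] = class_restrictions.get(c, 0) + nr
                cu = class_usages.setdefault(c, {})
                for p, k in us.items():
                    cu[p] = cu.get(p, 0) + k
        n_ann = 0
        for p, o in rdf.predicate_objects(subj):
            p_str = str(p)
            if p_str in annotation_predicates:
                n_ann += 1
                if p == RDFS.label and isinstance(o, Literal) and str(o).startswith(
                    OBSOLETE_LABEL_PREFIX
                ):
                    deprecated.add(c)
            elif p_str in deprecation_predicates:
                if not isinstance(o, Literal) or o.toPython() not in (False, "false", 0):
                    deprecated.add(c)
        if n_ann:
            annotations[c] = n_ann

    # individuals and property assertions, attributed to the individual's class
    individuals: dict[str, int] = {}
    assertion_usages: dict[str, dict[str, int]] = {}
    class_of: dict[str, str] = {}
    for i, o in rdf.subject_objects(RDF.type):
        if not isinstance(i, URIRef):
            continue
        i_str, o_str = str(i), str(o)
        if o_str in classes and i_str not in classes:
            # deterministic choice if an individual has several class types
            if i_str not in class_of or o_str < class_of[i_str]:
                class_of[i_str] = o_str
    for i_str, c in class_of.items():
        individuals[c] = individuals.get(c, 0) + 1
    all_props = object_properties | data_properties
    for i_str, c in class_of.items():
        for p, _o in rdf.predicate_objects(URIRef(i_str)):
            if str(p) in all_props:
                au = assertion_usages.setdefault(c, {})
                au[str(p)] = au.get(str(p), 0) + 1

    return OntologyGraph(
        classes=classes,
        subclass_edges=subclass_edges,
        object_properties=object_properties,
        data_properties=data_properties,
        class_usages=class_usages,
        assertion_usages=assertion_usages,
        annotations=annotations,
        individuals=individuals,
        class_restrictions=class_restrictions,
        deprecated=deprecated,
    )


# ---------------------------------------------------------------------------
# normalisation

def normalise(graph: OntologyGraph, remove_deprecated: bool = True) -> OntologyGraph:
    """Remove deprecated classes and everything asserted about them.

    Children whose only parents were removed are re-attached to the implicit
    root, keeping the DAG connected so the path metrics stay defined.
    Idempotent; the identity on graphs without deprecated classes.
    """
    if not remove_deprecated or not graph.deprecated:
        out = graph.copy()
        if remove_deprecated:
            out.deprecated = set()
        return out
    doomed = set(graph.deprecated)
    keep = graph.classes - doomed
    edges = {(c, p) for c, p in graph.subclass_edges if c in keep and p not in doomed}
    # re-attachment to the root happens in __post_init__ for orphans
    return OntologyGraph(
        classes=keep,
        subclass_edges=edges,
        object_properties=set(graph.object_properties),
        data_properties=set(graph.data_properties),
        class_usages={c: dict(u) for c, u in graph.class_usages.items() if c in keep},
        assertion_usages={
            c: dict(u) for c, u in graph.assertion_usages.items() if c in keep
        },
        annotations={c: n for c, n in graph.annotations.items() if c in keep},
        individuals={c: n for c, n in graph.individuals.items() if c in keep},
        class_restrictions={
            c: n for c, n in graph.class_restrictions.items() if c in keep
        },
        deprecated=set(),
    )


# ---------------------------------------------------------------------------
# version diffing (the activity variables)

def diff_versions(prev: OntologyGraph, next: OntologyGraph) -> ActivityDelta:
    """Count added, deleted and modified classes between two versions.

    A shared class counts as modified when its local axiom/annotation
    fingerprint differs between the versions (both logical-axiom and
    annotation-only edits count).
    """
    new = next.classes - prev.classes
    deleted = prev.classes - next.classes
    shared = prev.classes & next.classes
    changed = sum(
        1 for c in shared if prev.fingerprint(c) != next.fingerprint(c)
    )
    return ActivityDelta(n_new=len(new), n_deleted=len(deleted), n_changed=changed)


def activity_table(deltas: Iterable[tuple[str, ActivityDelta]]):
    """Activity deltas as a DataFrame (columns: version, n_new, n_deleted, n_changed)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "version": v,
                "n_new": d.n_new,
                "n_deleted": d.n_deleted,
                "n_changed": d.n_changed,
            }
            for v, d in deltas
        ]
    )
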