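"""Parameterised generator of small biomedical-style ontologies.

The generator emulates the structural features the metrics measure: an is-a
DAG of named classes under the implicit root with a controllable depth and
multiple-inheritance fraction, object/data properties with controllable
axiom-usage counts, annotation assertions, individuals with property
assertions, restriction axioms and deprecation flags.  Every generated
artefact carries an exactly book-kept ground-truth record, so the metric,
scaling and evolution layers can be tested against construction-time truth
rather than against themselves.

Mutation plans produce successor versions together with the exact activity
delta (classes added / deleted / modified) they induce, emulating the
change types a version-diff tool observes between ontology releases.

All randomness flows from the explicit seeds; the same seed reproduces a
byte-identical corpus.  IRIs are minted deterministically (namespace plus
zero-padded counters) so diffs and fingerprints are stable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import rdflib
from rdflib import OWL, RDF, RDFS, BNode, Literal, URIRef

from .errors import InapplicablePlanError
from .ontology_model import ROOT, ActivityDelta, OntologyGraph

NAMESPACE = "http://example.org/synthetic#"


@dataclass(frozen=True)
class GeneratorParams:
    """Construction parameters; the defaults describe a small curated
    biomedical vocabulary: a six-level hierarchy, light multiple
    inheritance (about 10 % of classes), a handful of properties, roughly
    one annotation per class, sparse restrictions and instances, and a few
    percent of deprecated classes."""

    n_classes: int = 60
    depth: int = 6
    multi_parent_fraction: float = 0.10
    n_object_properties: int = 4
    n_data_properties: int = 2
    usage_density: float = 0.5       # individual property assertions per class
    annotation_rate: float = 1.0     # annotation assertions per class
    individual_rate: float = 0.2     # individuals per class
    restriction_rate: float = 0.3    # restriction axioms per class
    deprecation_rate: float = 0.05   # fraction of classes flagged obsolete
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not (1 <= self.depth <= self.n_classes):
            raise ValueError("depth must be between 1 and n_classes")
        for name in ("multi_parent_fraction", "deprecation_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("usage_density", "annotation_rate", "individual_rate",
                     "restriction_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact construction-time counts and the metric values they imply."""

    n_classes: int
    depth: int
    multi_parent_count: int
    named_edges: int
    annotations_total: int
    restrictions_total: int
    usages_total: int
    individuals_total: int
    tm_fraction: float
    anonto: float
    aronto: float
    nomonto: float
    inronto: float
    cronto: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _class_iri(i: int) -> str:
    return f"{NAMESPACE}C{i:04d}"


def generate_ontology(p: GeneratorParams) -> tuple[OntologyGraph, GroundTruth]:
    """Build a DAG level by level and record exact expected metric values.

    A backbone chain of ``depth`` classes guarantees the hierarchy depth
    exactly; remaining classes attach to a random class one level up, and a
    ``multi_parent_fraction`` of eligible classes receives a second parent
    from a strictly shallower level (so no mutation can create a cycle or
    deepen the hierarchy).
    """
    rng = random.Random(p.seed)
    n = p.n_classes
    classes = [_class_iri(i + 1) for i in range(n)]
    level: dict[str, int] = {}
    by_level: dict[int, list[str]] = {d: [] for d in range(1, p.depth + 1)}

    # backbone guarantees the construction depth
    for d in range(1, p.depth + 1):
        c = classes[d - 1]
        level[c] = d
        by_level[d].append(c)
    for c in classes[p.depth:]:
        d = rng.randint(1, p.depth)
        level[c] = d
        by_level[d].append(c)

    edges: set[tuple[str, str]] = set()
    first_parent: dict[str, str] = {}
    for d in range(2, p.depth + 1):
        backbone = classes[d - 1]
        edges.add((backbone, classes[d - 2]))
        first_parent[backbone] = classes[d - 2]
    for c in classes[p.depth:]:
        d = level[c]
        if d == 1:
            continue  # implicit root child
        parent = rng.choice(by_level[d - 1])
        edges.add((c, parent))
        first_parent[c] = parent

    # second parents: classes at level >= 2 with an alternative candidate
    eligible = []
    for c in classes:
        if level[c] < 2:
            continue
        candidates = [
            q
            for d in range(1, level[c])
            for q in by_level[d]
            if q != first_parent.get(c) and q != c
        ]
        if candidates:
            eligible.append((c, candidates))
    target_multi = round(p.multi_parent_fraction * n)
    rng.shuffle(eligible)
    multi_parent = 0
    for c, candidates in eligible[:target_multi]:
        edges.add((c, rng.choice(candidates)))
        multi_parent += 1

    obj_props = [f"{NAMESPACE}op{i + 1:02d}" for i in range(p.n_object_properties)]
    data_props = [f"{NAMESPACE}dp{i + 1:02d}" for i in range(p.n_data_properties)]
    all_props = obj_props + data_props

    annotations: dict[str, int] = {}
    for _ in range(round(p.annotation_rate * n)):
        c = rng.choice(classes)
        annotations[c] = annotations.get(c, 0) + 1
    annotations_total = sum(annotations.values())

    class_restrictions: dict[str, int] = {}
    class_usages: dict[str, dict[str, int]] = {}
    restrictions_total = 0
    if all_props:
        for _ in range(round(p.restriction_rate * n)):
            c = rng.choice(classes)
            prop = rng.choice(all_props)
            class_restrictions[c] = class_restrictions.get(c, 0) + 1
            cu = class_usages.setdefault(c, {})
            cu[prop] = cu.get(prop, 0) + 1
            restrictions_total += 1

    individuals: dict[str, int] = {}
    for _ in range(round(p.individual_rate * n)):
        c = rng.choice(classes)
        individuals[c] = individuals.get(c, 0) + 1
    individuals_total = sum(individuals.values())

    assertion_usages: dict[str, dict[str, int]] = {}
    assertions_total = 0
    if individuals_total and all_props:
        populated = sorted(individuals)
        for _ in range(round(p.usage_density * n)):
            c = rng.choice(populated)
            prop = rng.choice(all_props)
            au = assertion_usages.setdefault(c, {})
            au[prop] = au.get(prop, 0) + 1
            assertions_total += 1

    deprecated = set(rng.sample(classes, round(p.deprecation_rate * n)))

    graph = OntologyGraph(
        classes=set(classes),
        subclass_edges=edges,
        object_properties=set(obj_props),
        data_properties=set(data_props),
        class_usages=class_usages,
        assertion_usages=assertion_usages,
        annotations=annotations,
        individuals=individuals,
        class_restrictions=class_restrictions,
        deprecated=deprecated,
    )
    usages_total = restrictions_total + assertions_total
    truth = GroundTruth(
        n_classes=n,
        depth=p.depth,
        multi_parent_count=multi_parent,
        named_edges=len(graph.named_edges),
        annotations_total=annotations_total,
        restrictions_total=restrictions_total,
        usages_total=usages_total,
        individuals_total=individuals_total,
        tm_fraction=multi_parent / n,
        anonto=annotations_total / n,
        aronto=restrictions_total / n,
        nomonto=usages_total / n,
        inronto=len(graph.named_edges) / n,
        cronto=individuals_total / n,
    )
    return graph, truth


# ---------------------------------------------------------------------------
# mutation

#: Recognised mutation operators, applied in this fixed order.
MUTATION_OPS = (
    "add_class",
    "delete_class",
    "deprecate_class",
    "add_restriction",
    "edit_annotation",
    "add_usage",
)


@dataclass(frozen=True)
class MutationPlan:
    """Multiplicities for each mutation operator plus a seed."""

    operations: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.operations) - set(MUTATION_OPS)
        if unknown:
            raise ValueError(f"unknown mutation operators: {sorted(unknown)}")
        if any(v < 0 for v in self.operations.values()):
            raise ValueError("operation multiplicities must be non-negative")


def mutate_version(
    g: OntologyGraph, plan: MutationPlan
) -> tuple[OntologyGraph, ActivityDelta]:
    """Apply a mutation plan, returning the successor and its exact delta.

    Modification operators touch pairwise-distinct surviving classes, so
    ``n_changed`` equals the number of modification operations; deletions
    pick leaves (their removal alters no other class's local axioms); new
    classes attach below an existing class or the root.
    """
    rng = random.Random(plan.seed)
    out = g.copy()
    ops = {op: plan.operations.get(op, 0) for op in MUTATION_OPS}

    untouched = sorted(out.classes)  # surviving, not-yet-modified classes
    rng.shuffle(untouched)

    def take(n: int, predicate=None) -> list[str]:
        picked, rest = [], []
        for c in untouched:
            if len(picked) < n and (predicate is None or predicate(c)):
                picked.append(c)
            else:
                rest.append(c)
        if len(picked) < n:
            raise InapplicablePlanError(
                f"not enough eligible classes for the plan (needed {n})"
            )
        untouched[:] = rest
        return picked

    # deletions first: leaves only, so nobody else's fingerprint moves
    parents_of = {p for _, p in out.named_edges}
    doomed = take(ops["delete_class"], lambda c: c not in parents_of)
    for c in doomed:
        out.classes.discard(c)
        out.subclass_edges = {(a, b) for a, b in out.subclass_edges if a != c}
        for table in (out.class_usages, out.assertion_usages, out.annotations,
                      out.individuals, out.class_restrictions):
            table.pop(c, None)
        out.deprecated.discard(c)

    all_props = sorted(out.object_properties | out.data_properties)

    for c in take(ops["deprecate_class"], lambda c: c not in out.deprecated):
        out.deprecated.add(c)
    if ops["add_restriction"]:
        if not all_props:
            raise InapplicablePlanError("add_restriction requires declared properties")
        for c in take(ops["add_restriction"]):
            out.class_restrictions[c] = out.class_restrictions.get(c, 0) + 1
            cu = out.class_usages.setdefault(c, {})
            prop = rng.choice(all_props)
            cu[prop] = cu.get(prop, 0) + 1
    for c in take(ops["edit_annotation"]):
        out.annotations[c] = out.annotations.get(c, 0) + 1
    if ops["add_usage"]:
        if not all_props:
            raise InapplicablePlanError("add_usage requires declared properties")
        for c in take(ops["add_usage"], lambda c: out.individuals.get(c, 0) > 0):
            au = out.assertion_usages.setdefault(c, {})
            prop = rng.choice(all_props)
            au[prop] = au.get(prop, 0) + 1

    existing = sorted(out.classes)
    idx = len(g.classes) + 1
    for _ in range(ops["add_class"]):
        while _class_iri(idx) in out.classes or _class_iri(idx) in g.classes:
            idx += 1
        new = _class_iri(idx)
        idx += 1
        parent = rng.choice(existing) if existing else ROOT
        out.classes.add(new)
        out.subclass_edges.add((new, parent))
        existing.append(new)

    n_changed = ops["deprecate_class"] + ops["add_restriction"] + ops["edit_annotation"] + ops["add_usage"]
    successor = OntologyGraph(
        classes=out.classes,
        subclass_edges=out.subclass_edges,
        object_properties=out.object_properties,
        data_properties=out.data_properties,
        class_usages=out.class_usages,
        assertion_usages=out.assertion_usages,
        annotations=out.annotations,
        individuals=out.individuals,
        class_restrictions=out.class_restrictions,
        deprecated=out.deprecated,
    )
    delta = ActivityDelta(
        n_new=ops["add_class"], n_deleted=ops["delete_class"], n_changed=n_changed
    )
    return successor, delta


# ---------------------------------------------------------------------------
# OWL writer

def _to_rdflib(g: OntologyGraph) -> rdflib.Graph:
    rdf = rdflib.Graph()
    rdf.bind("owl", OWL)
    # deterministic blank-node labels keep the serialisation byte-stable
    counter = iter(range(10**9))

    def bnode() -> BNode:
        return BNode(f"b{next(counter):06d}")
    for prop in sorted(g.object_properties):
        rdf.add((URIRef(prop), RDF.type, OWL.ObjectProperty))
    for prop in sorted(g.data_properties):
        rdf.add((URIRef(prop), RDF.type, OWL.DatatypeProperty))
    for c in sorted(g.classes):
        subj = URIRef(c)
        rdf.add((subj, RDF.type, OWL.Class))
        for _, p in sorted(e for e in g.subclass_edges if e[0] == c):
            rdf.add((subj, RDFS.subClassOf, OWL.Thing if p == ROOT else URIRef(p)))
        for i in range(g.annotations.get(c, 0)):
            rdf.add((subj, RDFS.comment, Literal(f"annotation {i}")))
        for prop, count in sorted(g.class_usages.get(c, {}).items()):
            is_obj = prop in g.object_properties
            for _ in range(count):
                node = bnode()
                rdf.add((subj, RDFS.subClassOf, node))
                rdf.add((node, RDF.type, OWL.Restriction))
                rdf.add((node, OWL.onProperty, URIRef(prop)))
                if is_obj:
                    rdf.add((node, OWL.someValuesFrom, OWL.Thing))
                else:
                    rdf.add((node, OWL.hasValue, Literal("v")))
        locals_ = [URIRef(f"{c}_i{j + 1}") for j in range(g.individuals.get(c, 0))]
        for ind in locals_:
            rdf.add((ind, RDF.type, OWL.NamedIndividual))
            rdf.add((ind, RDF.type, subj))
        slot = 0
        for prop, count in sorted(g.assertion_usages.get(c, {}).items()):
            if not locals_:
                raise ValueError(
                    f"class {c} has property assertions but no individuals"
                )
            is_obj = prop in g.object_properties
            for k in range(count):
                ind = locals_[slot % len(locals_)]
                slot += 1
                if is_obj:
                    rdf.add((ind, URIRef(prop), bnode()))
                else:
                    rdf.add((ind, URIRef(prop), Literal(f"v{slot}")))
        if c in g.deprecated:
            rdf.add((subj, OWL.deprecated, Literal(True)))
    return rdf


def write_ontology(g: OntologyGraph, path, dialect: str = "auto") -> Path:
    """Serialise a graph as OWL RDF/XML or Turtle.

    The writer realises each count as distinct triples, so
    ``read_ontology(write_ontology(g)) == g``.  It assumes each restriction
    uses exactly one property, i.e. per class the restriction count equals
    the total class-axiom usage count — which holds for every
    generator-produced graph.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "turtle" if path.suffix.lower() in {".ttl", ".n3"} else "rdfxml"
    fmt = {"rdfxml": "xml", "turtle": "turtle"}[dialect]
    _to_rdflib(g).serialize(destination=str(path), format=fmt)
    return path


# ---------------------------------------------------------------------------
# corpora

def generate_corpus(
    params: GeneratorParams,
    plans: Sequence[MutationPlan],
) -> tuple[list[OntologyGraph], list[ActivityDelta], GroundTruth]:
    """Base ontology plus one successor per plan, with exact deltas."""
    base, truth = generate_ontology(params)
    graphs = [base]
    deltas = []
    for plan in plans:
        nxt, delta = mutate_version(graphs[-1], plan)
        graphs.append(nxt)
        deltas.append(delta)
    return graphs, deltas, truth


def write_corpus(
    graphs: Sequence[OntologyGraph],
    directory,
    dialect: str = "rdfxml",
    manifest_extra: Optional[dict] = None,
) -> list[Path]:
    """Write ``v001.owl .. vNNN.owl`` plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".ttl" if dialect == "turtle" else ".owl"
    paths = []
    for i, g in enumerate(graphs, start=1):
        paths.append(write_ontology(g, directory / f"v{i:03d}{suffix}", dialect))
    manifest = {
        "versions": [p.name for p in paths],
        "dialect": dialect,
        **(manifest_extra or {}),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
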