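import pytest

from oquare import GeneratorParams, OntologyGraph, generate_ontology

NS = "http://example.org/synthetic#"


def iri(name: str) -> str:
    return NS + name


@pytest.fixture
def chain_graph():
    """root -> A -> B."""
    return OntologyGraph(
        classes={iri("A"), iri("B")},
        subclass_edges={(iri("B"), iri("A"))},
    )


@pytest.fixture
def diamond_graph():
    """7-class DAG with one diamond: D has parents B and C (both under A);
    E, F, G extend a side chain below D."""
    A, B, C, D, E, F, G = (iri(x) for x in "ABCDEFG")
    return OntologyGraph(
        classes={A, B, C, D, E, F, G},
        subclass_edges={
            (B, A), (C, A), (D, B), (D, C), (E, D), (F, E), (G, A),
        },
    )


@pytest.fixture
def small_generated():
    return generate_ontology(GeneratorParams(n_classes=30, depth=4, seed=11))
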