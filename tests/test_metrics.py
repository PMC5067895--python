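"""Raw metric values against exhaustive and construction-time oracles."""


import networkx as nx
import pytest

from oquare import (
    GeneratorParams,
    OntologyGraph,
    ROOT,
    compute_metrics,
    generate_ontology,
    normalise,
)
from oquare.errors import PathExplosionError

from conftest import iri


def exhaustive_path_lengths(graph):
    """Oracle: enumerate every distinct leaf-to-root path with networkx."""
    dag = nx.DiGraph()
    for c, p in graph.subclass_edges:
        dag.add_edge(c, p)
    lengths = []
    for leaf in graph.leaves:
        for path in nx.all_simple_paths(dag, leaf, ROOT):
            lengths.append(len(path) - 1)
    return lengths


class TestChainAndDiamond:
    def test_chain_values(self, chain_graph):
        m = compute_metrics(chain_graph)
        assert m["DITOnto"] == 2
        assert m["TMOnto"] == 0
        assert m["LCOMOnto"] == 2
        assert m["NOMOnto"] == 0
        assert m["RROnto"] == 0

    def test_diamond_path_enumeration_oracle(self, diamond_graph):
        m = compute_metrics(diamond_graph)
        lengths = exhaustive_path_lengths(diamond_graph)
        assert m["LCOMOnto"] == pytest.approx(sum(lengths) / len(lengths))
        assert m["DITOnto"] == max(lengths)

    def test_single_class(self):
        g = OntologyGraph(classes={iri("A")})
        m = compute_metrics(g)
        assert m["DITOnto"] == 1
        assert m["LCOMOnto"] == 1
        assert m["TMOnto"] == 0
        # every class is a direct root child: denominator vanishes
        assert m["CBOnto"] is None

    def test_empty_graph_is_all_undefined(self):
        m = compute_metrics(OntologyGraph())
        assert all(v is None for v in m.as_dict().values())


class TestAgainstGenerators:
    @pytest.mark.parametrize("seed", range(5))
    def test_count_metrics_match_ground_truth(self, seed):
        g, truth = generate_ontology(
            GeneratorParams(n_classes=40, depth=5, multi_parent_fraction=0.25,
                            seed=seed)
        )
        m = compute_metrics(g)
        assert m["TMOnto"] == truth.tm_fraction
        assert m["ANOnto"] == truth.anonto
        assert m["AROnto"] == truth.aronto
        assert m["NOMOnto"] == truth.nomonto
        assert m["INROnto"] == truth.inronto
        assert m["CROnto"] == truth.cronto
        assert m["DITOnto"] == truth.depth

    def test_multi_parent_fraction_fixture(self):
        # 10-class DAG engineered to have exactly 2 multi-parent classes,
        # cross-checked by brute-force parent counting
        g, truth = generate_ontology(
            GeneratorParams(n_classes=10, depth=3, multi_parent_fraction=0.2,
                            seed=4)
        )
        brute = sum(
            1 for c in g.classes
            if sum(1 for e in g.subclass_edges if e[0] == c) > 1
        )
        assert brute == truth.multi_parent_count == 2
        assert compute_metrics(g)["TMOnto"] == 0.2

    def test_pure_tree_lcom_equals_mean_leaf_depth(self):
        g, _ = generate_ontology(
            GeneratorParams(n_classes=30, depth=4, multi_parent_fraction=0.0,
                            seed=9)
        )
        m = compute_metrics(g)
        assert m["TMOnto"] == 0
        lengths = exhaustive_path_lengths(g)
        assert m["LCOMOnto"] == pytest.approx(sum(lengths) / len(lengths))

    @pytest.mark.parametrize("seed", range(4))
    def test_path_metrics_agree_with_exhaustive_oracle(self, seed):
        g, _ = generate_ontology(
            GeneratorParams(n_classes=50, depth=6, multi_parent_fraction=0.3,
                            seed=seed)
        )
        m = compute_metrics(g)
        lengths = exhaustive_path_lengths(g)
        assert m["LCOMOnto"] == pytest.approx(sum(lengths) / len(lengths))
        assert m["DITOnto"] == max(lengths)

    def test_normalise_noop_preserves_metrics(self):
        g, _ = generate_ontology(
            GeneratorParams(n_classes=25, depth=4, deprecation_rate=0.0, seed=2)
        )
        assert compute_metrics(normalise(g)).as_dict() == compute_metrics(g).as_dict()


class TestMonotonicity:
    def test_annotation_strictly_increases_anonto(self, small_generated):
        g, _ = small_generated
        before = compute_metrics(g)["ANOnto"]
        c = sorted(g.classes)[0]
        g2 = g.copy()
        g2.annotations[c] = g2.annotations.get(c, 0) + 1
        assert compute_metrics(g2)["ANOnto"] > before

    def test_second_parent_strictly_increases_tmonto(self, diamond_graph):
        before = compute_metrics(diamond_graph)["TMOnto"]
        g2 = diamond_graph.copy()
        g2.subclass_edges.add((iri("G"), iri("B")))  # G had a single parent
        g2 = OntologyGraph(
            classes=g2.classes, subclass_edges=g2.subclass_edges
        )
        assert compute_metrics(g2)["TMOnto"] > before


def test_path_cap_raises_instead_of_hanging():
    # layered graph where every class has two parents: path count doubles
    # per level, exceeding a tiny cap
    layers = [[iri(f"L{d}_{j}") for j in range(2)] for d in range(8)]
    edges = set()
    for below, above in zip(layers[1:], layers):
        for c in below:
            for p in above:
                edges.add((c, p))
    g = OntologyGraph(
        classes={c for layer in layers for c in layer}, subclass_edges=edges
    )
    with pytest.raises(PathExplosionError):
        compute_metrics(g, max_paths=50)
    assert compute_metrics(g, max_paths=10**6)["LCOMOnto"] == pytest.approx(
        sum(exhaustive_path_lengths(g)) / len(exhaustive_path_lengths(g))
    )


def test_cyclic_graph_is_rejected():
    g = OntologyGraph(classes={iri("A"), iri("B")})
    g.subclass_edges = {(iri("A"), iri("B")), (iri("B"), iri("A"))}
    from oquare import StructuralError

    with pytest.raises(StructuralError):
        compute_metrics(g)
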