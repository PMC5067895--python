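"""The 14 structural quality metrics.

Each metric summarises one structural aspect of an ontology: annotation
density (ANOnto), restriction density (AROnto), coupling (CBOnto), instance
density (CROnto), hierarchy depth (DITOnto), relationship density (INROnto),
ancestry of leaves (NACOnto), fan-out (NOCOnto), property-usage density
(NOMOnto), cohesion via leaf-to-root path lengths (LCOMOnto), response
surface (RFCOnto), relationship richness (RROnto), tangledness / multiple
inheritance (TMOnto) and overall weighted method count (WMCOnto).

Undefined values (zero denominators, empty ontologies) are reported as
``None`` markers, never as infinities; aggregation layers drop them with a
warning.

Conventions: path lengths are counted in edges; the implicit root is a path
endpoint but never a class; "subclasses of Thing" in denominators means the
direct children of the root; TMOnto is the *fraction* of classes with more
than one direct parent, so it lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import PathExplosionError
from .ontology_model import ROOT, OntologyGraph

#: Canonical metric order, used for vectors and tables.
METRIC_IDS = (
    "ANOnto",
    "AROnto",
    "CBOnto",
    "CROnto",
    "DITOnto",
    "INROnto",
    "NACOnto",
    "NOCOnto",
    "NOMOnto",
    "LCOMOnto",
    "RFCOnto",
    "RROnto",
    "TMOnto",
    "WMCOnto",
)

#: Default cap on the number of distinct leaf-to-root paths enumerated for
#: LCOMOnto.  Multi-parent classes multiply path counts, so heavily tangled
#: graphs can explode combinatorially.
DEFAULT_MAX_PATHS = 10**6


@dataclass(frozen=True)
class MetricVector:
    """The 14 raw metric values of one version; ``None`` marks undefined."""

    values: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(METRIC_IDS)
        if unknown:
            raise ValueError(f"unknown metric ids: {sorted(unknown)}")

    def __getitem__(self, metric_id: str) -> Optional[float]:
        if metric_id not in METRIC_IDS:
            raise KeyError(metric_id)
        return self.values.get(metric_id)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {m: self.values.get(m) for m in METRIC_IDS}


def _path_statistics(graph: OntologyGraph, max_paths: int) -> tuple[int, int, int]:
    """Return (number of leaf-to-root paths, total edge length, max depth).

    Dynamic programme over the DAG: for each class, the number of distinct
    paths to the root and their total length; multi-parent classes contribute
    one path per parent path.  Polynomial in the path count, capped.
    """
    n_paths: dict[str, int] = {}
    tot_len: dict[str, int] = {}
    depth: dict[str, int] = {}

    order = _topological_order(graph)
    for c in order:
        parents = graph.parents(c)
        np_, tl, d = 0, 0, 0
        for p in parents:
            if p == ROOT:
                np_ += 1
                tl += 1
                d = max(d, 1)
            else:
                np_ += n_paths[p]
                tl += tot_len[p] + n_paths[p]
                d = max(d, depth[p] + 1)
        n_paths[c], tot_len[c], depth[c] = np_, tl, d
        if np_ > max_paths:
            raise PathExplosionError(
                f"more than {max_paths} leaf-to-root paths; raise max_paths to proceed"
            )
    leaves = graph.leaves
    total_paths = sum(n_paths[c] for c in leaves)
    if total_paths > max_paths:
        raise PathExplosionError(
            f"more than {max_paths} leaf-to-root paths; raise max_paths to proceed"
        )
    total_length = sum(tot_len[c] for c in leaves)
    max_depth = max((depth[c] for c in graph.classes), default=0)
    return total_paths, total_length, max_depth


def _topological_order(graph: OntologyGraph) -> list[str]:
    # parents before children: order by DAG over named edges (child -> parent)
    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(graph.classes)
    for c, p in graph.named_edges:
        dag.add_edge(p, c)
    return list(nx.topological_sort(dag))


def compute_metrics(
    graph: OntologyGraph, max_paths: int = DEFAULT_MAX_PATHS
) -> MetricVector:
    """Compute the 14 raw metric values of one ontology version.

    Zero-denominator metrics (e.g. CBOnto when every class is a direct child
    of the root) are reported as ``None``.  An empty ontology yields an
    all-undefined vector.
    """
    graph.validate()
    n = len(graph.classes)
    if n == 0:
        return MetricVector({m: None for m in METRIC_IDS})

    edges_all = len(graph.subclass_edges)
    edges_named = len(graph.named_edges)
    root_children = len(graph.root_children)
    usages = graph.total_usages
    n_props = len(graph.object_properties) + len(graph.data_properties)
    leaves = graph.leaves

    n_paths, total_len, max_depth = _path_statistics(graph, max_paths)

    def ratio(num: float, den: float) -> Optional[float]:
        return num / den if den else None

    multi_parent = sum(1 for c in graph.classes if len(graph.parents(c)) > 1)
    non_root_den = n - root_children  # classes minus direct subclasses of Thing

    values: dict[str, Optional[float]] = {
        "ANOnto": sum(graph.annotations.values()) / n,
        "AROnto": graph.restrictions / n,
        "CBOnto": ratio(edges_all, non_root_den),
        "CROnto": sum(graph.individuals.values()) / n,
        "DITOnto": max_depth,
        "INROnto": edges_named / n,
        "NACOnto": ratio(
            sum(len(graph.parents(c)) for c in leaves), len(leaves)
        ),
        "NOCOnto": ratio(edges_all, non_root_den),
        "NOMOnto": usages / n,
        "LCOMOnto": ratio(total_len, n_paths),
        "RFCOnto": ratio(usages + edges_all, non_root_den),
        "RROnto": ratio(usages, edges_all + n_props),
        "TMOnto": multi_parent / n,
        "WMCOnto": (usages + edges_all) / n,
    }
    return MetricVector(values)


def metric_table(rows: Iterable[tuple[str, MetricVector]]):
    """Raw-metric table: one row per version, one column per metric."""
    import pandas as pd

    return pd.DataFrame(
        [{"version": v, **m.as_dict()} for v, m in rows]
    ).set_index("version")
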