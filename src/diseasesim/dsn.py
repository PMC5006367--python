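"""Disease similarity network (DSN) construction.

The DSN keeps only the strongest signal: the top fraction (0.5 % by
default) of all pairwise similarity scores become undirected weighted
edges; diseases left without any edge are dropped.  Nodes carry
top-level ontology categories (the root's children above each disease)
for coloring in external viewers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io import OntologyDAG, SimilarityTable

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseSimilarityNetwork", "build_dsn", "top_level_category",
    "annotate_categories", "write_dsn",
]


@dataclass
class DiseaseSimilarityNetwork:
    """Top-ranked similarity edges with per-node category labels."""

    edges: list[tuple[str, str, float]]
    nodes: list[str]
    categories: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def primary_category(self, disease: str) -> str | None:
        """Lexicographically first category, for single-color rendering."""
        cats = self.categories.get(disease)
        return min(cats) if cats else None

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for node in self.nodes:
            cats = sorted(self.categories.get(node, ()))
            g.add_node(node, categories="|".join(cats),
                       primary_category=self.primary_category(node) or "")
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def build_dsn(table: SimilarityTable,
              top_fraction: float = 0.005) -> DiseaseSimilarityNetwork:
    """Keep the ``floor(top_fraction · N)`` highest-scoring pairs as edges.

    Ties at the cutoff are broken by canonical pair order so the edge
    set is deterministic.  ``top_fraction`` small enough that no pair
    survives yields an empty network with a warning.
    """
    if len(table) == 0:
        raise ValueError("similarity table is empty")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    k = math.floor(top_fraction * len(table))
    if k == 0:
        logger.warning(
            "top_fraction %.4g of %d pairs keeps no edge", top_fraction,
            len(table),
        )
        return DiseaseSimilarityNetwork(edges=[], nodes=[])
    ranked = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    edges = [(a, b, score) for (a, b), score in ranked[:k]]
    nodes = sorted({d for a, b, _ in edges for d in (a, b)})
    return DiseaseSimilarityNetwork(edges=edges, nodes=nodes)


def top_level_category(dag: OntologyDAG, disease: str) -> set[str]:
    """Root children that are ancestors-or-self of ``disease``.

    A multi-parent DAG can place a disease under several top-level
    categories; all are returned.  A disease not connected to the root
    gets an empty set (logged).
    """
    if disease not in dag.terms:
        raise KeyError(f"disease {disease!r} not in ontology")
    if dag.root_id is None:
        raise ValueError("ontology has no unique root")
    top_level = dag.children(dag.root_id)
    cats = dag.ancestors_or_self(disease) & top_level
    if not cats and disease != dag.root_id:
        logger.warning("disease %s is not under the ontology root", disease)
    return cats


def annotate_categories(dsn: DiseaseSimilarityNetwork,
                        dag: OntologyDAG) -> DiseaseSimilarityNetwork:
    """Attach top-level categories to every DSN node present in the DAG."""
    for node in dsn.nodes:
        if node in dag.terms:
            dsn.categories[node] = top_level_category(dag, node)
        else:
            logger.warning("DSN node %s missing from ontology", node)
            dsn.categories[node] = set()
    return dsn


def write_dsn(dsn: DiseaseSimilarityNetwork, edge_path: str,
              node_path: str, graphml_path: str | None = None) -> None:
    """Write edge and node TSVs (and optionally GraphML for viewers)."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("#disease1\tdisease2\tweight\n")
        for a, b, w in dsn.edges:
            fh.write(f"{a}\t{b}\t{w!r}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("#disease\tcategories\tprimary_category\n")
        for node in dsn.nodes:
            cats = "|".join(sorted(dsn.categories.get(node, ())))
            fh.write(f"{node}\t{cats}\t{dsn.primary_category(node) or ''}\n")
    if graphml_path is not None:
        import networkx as nx
        nx.write_graphml(dsn.to_networkx(), graphml_path)
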