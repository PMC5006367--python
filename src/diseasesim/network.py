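"""Random walk with restart and network-based disease similarity (NetSim).

The walker model: with probability ``r`` jump back to a seed gene, with
probability ``1 - r`` step to a uniformly chosen network neighbor.  The
steady state ``p`` solves ``p = r·e + (1 − r)·T·p`` where
``T = A·D⁻¹`` is the column-stochastic transition matrix (every gene
spreads its probability equally over its neighbors, conserving total
mass) and ``e`` carries 1.0 at every in-network seed gene.  The
steady-state value of a gene measures its proximity to the seed set;
NetSim averages these *functional relevances* across two diseases'
gene sets in both directions.

Genes absent from the network are still meaningful: a gene outside the
network that belongs to the other disease's gene set contributes
relevance 1, any other off-network gene contributes 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork", "NetSimParams", "RWRResult",
    "rwr", "functional_relevance", "netsim", "netsim_matrix",
    "rwr_call_count", "reset_rwr_call_count",
]

# Process-wide counter of RWR solves; lets callers verify caching
# contracts (one solve per distinct disease in batch mode).
_RWR_CALLS = 0


def rwr_call_count() -> int:
    return _RWR_CALLS


def reset_rwr_call_count() -> None:
    global _RWR_CALLS
    _RWR_CALLS = 0


class InteractionNetwork:
    """Undirected simple graph over gene identifiers.

    Stores an ordered node list, a symmetric 0/1 sparse adjacency with
    zero diagonal, and per-node degrees.
    """

    def __init__(self, nodes: Sequence[str], adjacency: sp.spmatrix):
        self.nodes: list[str] = list(nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        adj = sp.csr_matrix(adjacency, dtype=np.float64)
        if adj.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if adj.diagonal().any():
            raise ValueError("adjacency has a nonzero diagonal (self-loop)")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        self.adjacency = adj
        self.degree = np.asarray(adj.sum(axis=0)).ravel()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Sequence[str] | None = None) -> "InteractionNetwork":
        """Build from undirected edges; duplicates and reversals collapse."""
        edge_set: set[tuple[str, str]] = set()
        seen: list[str] = []
        seen_set: set[str] = set()
        for a, b in edges:
            if a == b:
                logger.warning("dropping self-loop on %r", a)
                continue
            for g in (a, b):
                if g not in seen_set:
                    seen_set.add(g)
                    seen.append(g)
            edge_set.add((a, b) if a <= b else (b, a))
        node_list = list(nodes) if nodes is not None else sorted(seen)
        index = {g: i for i, g in enumerate(node_list)}
        rows, cols = [], []
        for a, b in edge_set:
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
        n = len(node_list)
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        return cls(node_list, adj)

    @classmethod
    def from_networkx(cls, graph) -> "InteractionNetwork":
        nodes = sorted(graph.nodes())
        return cls.from_edges(graph.edges(), nodes=nodes)

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        coo = sp.triu(self.adjacency).tocoo()
        g.add_edges_from(
            (self.nodes[i], self.nodes[j]) for i, j in zip(coo.row, coo.col)
        )
        return g

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


@dataclass
class NetSimParams:
    """Tunables of the RWR solver.

    ``restart_prob`` defaults to 0.7, the convention of the RWR
    gene-prioritization literature; the steady state is found by power
    iteration, which contracts at rate ``1 − restart_prob``.  With
    ``normalize_seeds`` the restart vector is scaled to sum to one
    (probability-vector variant); the default keeps 1.0 per seed.
    """

    restart_prob: float = 0.7
    tolerance: float = 1e-9
    max_iterations: int = 1000
    normalize_seeds: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RWRResult:
    """Steady state of one RWR solve."""

    probabilities: dict[str, float]
    restart_prob: float
    seed_set: frozenset[str]
    converged: bool
    iterations: int
    residual: float = field(default=float("nan"))

    def __getitem__(self, gene: str) -> float:
        return self.probabilities[gene]


def rwr(network: InteractionNetwork, seeds: Iterable[str],
        params: NetSimParams | None = None) -> RWRResult:
    """Solve the RWR steady state for a seed gene set.

    Seeds outside the network are ignored for propagation; at least one
    seed must be a network node.  Columns of isolated (degree-0) nodes
    are replaced by the restart distribution so no probability mass is
    lost, keeping ``Σp = Σe``.
    """
    global _RWR_CALLS
    params = params or NetSimParams()
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    seed_set = frozenset(seeds)
    seed_idx = np.array(
        sorted(network.index[g] for g in seed_set if g in network.index),
        dtype=np.intp,
    )
    if seed_idx.size == 0:
        raise ValueError(
            "no seed gene is a network node; propagation undefined"
        )

    n = network.n_nodes
    e = np.zeros(n)
    e[seed_idx] = 1.0
    if params.normalize_seeds:
        e /= e.sum()
    e_hat = e / e.sum()  # restart distribution, reused for dangling columns

    r = params.restart_prob
    deg = network.degree
    isolated = deg == 0
    inv_deg = np.zeros(n)
    inv_deg[~isolated] = 1.0 / deg[~isolated]
    # T p = A D⁻¹ p for connected nodes; isolated nodes hand their mass
    # to the restart distribution.
    adj = network.adjacency

    p = e.copy()
    converged = False
    it = 0
    residual = np.inf
    for it in range(1, params.max_iterations + 1):
        step = adj.dot(p * inv_deg) if not isolated.all() else np.zeros(n)
        if isolated.any():
            step = step + e_hat * p[isolated].sum()
        p_next = r * e + (1.0 - r) * step
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual <= params.tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "RWR did not converge in %d iterations (residual %.3e)",
            params.max_iterations, residual,
        )
    _RWR_CALLS += 1
    probabilities = {g: float(p[i]) for g, i in network.index.items()}
    return RWRResult(
        probabilities=probabilities,
        restart_prob=r,
        seed_set=seed_set,
        converged=converged,
        iterations=it,
        residual=residual,
    )


def _fr(network: InteractionNetwork, gene_set: frozenset[str], gene: str,
        result: RWRResult | None) -> float:
    """Functional relevance of one gene given a precomputed RWR result."""
    if gene in network:
        if result is None:
            raise ValueError(
                "gene is a network node but the seed set has no network "
                "member; relevance undefined"
            )
        return result.probabilities[gene]
    return 1.0 if gene in gene_set else 0.0


def functional_relevance(network: InteractionNetwork,
                         gene_set: Iterable[str], gene: str,
                         params: NetSimParams | None = None,
                         rwr_result: RWRResult | None = None) -> float:
    """Relevance of ``gene`` to ``gene_set`` under network propagation.

    In-network genes get their RWR steady-state value (``rwr_result``
    may supply a cached solve seeded by ``gene_set``); off-network genes
    get 1 if they belong to ``gene_set``, else 0.
    """
    gene_set = frozenset(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    if gene in network and rwr_result is None:
        rwr_result = rwr(network, gene_set, params)
    return _fr(network, gene_set, gene, rwr_result)


def _netsim_from_results(network: InteractionNetwork,
                         g1: frozenset[str], g2: frozenset[str],
                         res1: RWRResult | None,
                         res2: RWRResult | None) -> float:
    total = 0.0
    for g in g1:
        total += _fr(network, g2, g, res2)
    for g in g2:
        total += _fr(network, g1, g, res1)
    return total / (len(g1) + len(g2))


def _maybe_rwr(network: InteractionNetwork, genes: frozenset[str],
               params: NetSimParams) -> RWRResult | None:
    """RWR seeded by ``genes``, or None when no seed is a network node."""
    if any(g in network for g in genes):
        return rwr(network, genes, params)
    return None


def netsim(network: InteractionNetwork, g1: Iterable[str], g2: Iterable[str],
           params: NetSimParams | None = None) -> float:
    """Network similarity of two gene sets.

    Averages the functional relevance of every gene in one set to the
    other set, over both directions; exactly two RWR solves are needed
    regardless of set sizes.  Empty sets are an error — similarity is
    undefined, which is distinct from a score of zero.
    """
    params = params or NetSimParams()
    g1, g2 = frozenset(g1), frozenset(g2)
    if not g1 or not g2:
        raise ValueError("both gene sets must be nonempty")
    res1 = _maybe_rwr(network, g1, params)
    res2 = _maybe_rwr(network, g2, params)
    return _netsim_from_results(network, g1, g2, res1, res2)


def netsim_matrix(network: InteractionNetwork,
                  gene_disease: Mapping[str, set[str]],
                  pairs: Iterable[tuple[str, str]],
                  params: NetSimParams | None = None):
    """NetSim for many disease pairs with one RWR solve per disease.

    Pairs whose diseases lack gene sets are skipped and logged.  Returns
    a :class:`~diseasesim.io.SimilarityTable`.
    """
    from .io import SimilarityTable, canonical_pair

    params = params or NetSimParams()
    cache: dict[str, RWRResult | None] = {}
    sets: dict[str, frozenset[str]] = {}
    table = SimilarityTable()
    skipped: list[tuple[str, str]] = []

    def _resolve(d: str) -> bool:
        if d in sets:
            return True
        genes = gene_disease.get(d)
        if not genes:
            return False
        sets[d] = frozenset(genes)
        cache[d] = _maybe_rwr(network, sets[d], params)
        return True

    for a, b in pairs:
        a, b = canonical_pair(a, b)
        if (a, b) in table:
            continue
        if not (_resolve(a) and _resolve(b)):
            skipped.append((a, b))
            continue
        score = _netsim_from_results(
            network, sets[a], sets[b], cache[a], cache[b]
        )
        table.set(a, b, score)
    if skipped:
        logger.warning("netsim_matrix skipped %d pairs lacking gene sets: %s",
                       len(skipped), skipped[:5])
    return table
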