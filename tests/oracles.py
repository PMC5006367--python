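"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or a direct
linear solve, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def rwr_linear_solve(network, seeds, restart_prob: float,
                     normalize_seeds: bool = False) -> np.ndarray:
    """Steady state by dense solve of (I − (1−r)·T)p = r·e.

    T = A·D⁻¹ is the column-stochastic transition matrix: each node
    spreads its probability equally over its neighbors, so total mass
    is conserved.  Columns of isolated nodes fall back to the restart
    distribution.
    """
    n = network.n_nodes
    adj = network.adjacency.toarray()
    e = np.zeros(n)
    for g in seeds:
        if g in network.index:
            e[network.index[g]] = 1.0
    if normalize_seeds:
        e = e / e.sum()
    e_hat = e / e.sum()
    col_sums = adj.sum(axis=0)
    w = np.zeros((n, n))
    for j in range(n):
        if col_sums[j] > 0:
            w[:, j] = adj[:, j] / col_sums[j]
        else:
            w[:, j] = e_hat
    r = restart_prob
    return np.linalg.solve(np.eye(n) - (1.0 - r) * w, r * e)


def auc_exhaustive(positives, negatives) -> float:
    """AUC by enumerating every (positive, negative) cross pair."""
    wins = 0.0
    for p in positives:
        for q in negatives:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(positives) * len(negatives))


# ---------------------------------------------------------------------------
# Ontology oracles
# ---------------------------------------------------------------------------

def ancestors_or_self_brute(dag, term) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in dag.graph.successors(node):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def descendants_or_self_brute(dag, term) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for child in dag.graph.predecessors(node):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


def ic_brute(dag, annotations) -> dict[str, float]:
    """IC by exhaustive descendant enumeration per term."""
    instances = [(e, t) for e, terms in annotations.items()
                 for t in set(terms)]
    total = len(instances)
    out = {}
    for term in dag.terms:
        desc = descendants_or_self_brute(dag, term)
        count = sum(1 for _, t in instances if t in desc)
        if count > 0:
            out[term] = -math.log(count / total)
    return out


def resnik_brute(t1, t2, dag, icmap) -> float:
    common = ancestors_or_self_brute(dag, t1) & ancestors_or_self_brute(dag, t2)
    return max((icmap[a] for a in common if a in icmap), default=0.0)


def lin_brute(t1, t2, dag, icmap) -> float:
    denom = icmap[t1] + icmap[t2]
    if denom == 0:
        return 0.0
    return 2.0 * resnik_brute(t1, t2, dag, icmap) / denom


def _svalues_paths(dag, term, w) -> dict[str, float]:
    """Wang S-values by explicit enumeration of all upward paths."""
    svals = {term: 1.0}

    def walk(node, value):
        for parent in dag.graph.successors(node):
            v = value * w
            if v > svals.get(parent, 0.0):
                svals[parent] = v
            walk(parent, v)

    walk(term, 1.0)
    return svals


def wang_brute(t1, t2, dag, w=0.8) -> float:
    s1 = _svalues_paths(dag, t1, w)
    s2 = _svalues_paths(dag, t2, w)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return (sum(s1[a] + s2[a] for a in common)
            / (sum(s1.values()) + sum(s2.values())))


def bma_brute(a1, a2, termsim) -> float:
    d12 = sum(max(termsim(s, t) for t in a2) for s in a1) / len(a1)
    d21 = sum(max(termsim(s, t) for t in a1) for s in a2) / len(a2)
    return 0.5 * (d12 + d21)


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random single-root DAG: term i picks 1–2 parents among 0..i−1."""
    import networkx as nx

    from diseasesim.io import OntologyDAG

    terms = {f"T{i:03d}": {"name": f"term {i}", "synonyms": []}
             for i in range(n_terms)}
    ids = sorted(terms)
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            graph.add_edge(ids[i], ids[int(p)])
    return OntologyDAG(terms=terms, graph=graph, root_id=ids[0])
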