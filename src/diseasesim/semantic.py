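"""Ontology-based baseline similarities.

Term-level measures over an IS_A DAG:

* **Resnik** — information content (IC) of the most informative common
  ancestor (MICA), where IC(t) = −ln p(t) and p(t) is the fraction of
  annotations falling on t or any of its descendants.
* **Lin** — 2·IC(MICA) / (IC(t1) + IC(t2)), normalizing Resnik by the
  terms' own ICs; in [0, 1].
* **Wang** — purely structural: every ancestor contributes a
  "semantic value" that decays by a contribution factor per IS_A edge;
  similarity is the overlap of the two terms' ancestor contributions.

Set-level similarity between two diseases' annotation sets uses the
best-match average (BMA): each term is matched to its best counterpart,
directional averages are symmetrized by averaging both directions.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping

import networkx as nx

from .io import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "information_content", "resnik", "lin", "wang", "bma_similarity",
    "annotation_ic", "structural_ic",
]

TermSim = Callable[[str, str], float]


def information_content(dag: OntologyDAG,
                        annotations: Mapping[str, Iterable[str]]) -> dict[str, float]:
    """Annotation-frequency IC map.

    Each (entity, term) annotation instance counts toward the term and
    every ancestor; IC(t) = −ln(count(t) / total).  Terms with zero
    propagated count are absent from the map (their IC is undefined).
    The root of a connected DAG gets IC 0.
    """
    instances = [
        (entity, term)
        for entity, terms in annotations.items()
        for term in set(terms)
    ]
    if not instances:
        raise ValueError("annotation corpus is empty")
    counts: dict[str, int] = {}
    for _, term in instances:
        if term not in dag.terms:
            raise KeyError(f"annotated term {term!r} not in ontology")
        for anc in dag.ancestors_or_self(term):
            counts[anc] = counts.get(anc, 0) + 1
    total = len(instances)
    # `+ 0.0` turns the root's −0.0 into a plain 0.0
    return {t: -math.log(c / total) + 0.0 for t, c in counts.items()}


annotation_ic = information_content


def structural_ic(dag: OntologyDAG) -> dict[str, float]:
    """Descendant-count IC fallback for ontologies without annotations.

    Treats every term as annotated once: p(t) = |descendants-or-self| / N.
    """
    n = dag.n_terms
    return {
        t: -math.log(len(dag.descendants_or_self(t)) / n) + 0.0
        for t in dag.terms
    }


def _common_ancestors(dag: OntologyDAG, t1: str, t2: str) -> set[str]:
    return dag.ancestors_or_self(t1) & dag.ancestors_or_self(t2)


def resnik(t1: str, t2: str, dag: OntologyDAG,
           icmap: Mapping[str, float]) -> float:
    """IC of the most informative common ancestor; 0 with no shared IC."""
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"term {t!r} not in ontology")
    common = _common_ancestors(dag, t1, t2)
    ics = [icmap[a] for a in common if a in icmap]
    return max(ics, default=0.0)


def lin(t1: str, t2: str, dag: OntologyDAG,
        icmap: Mapping[str, float]) -> float:
    """Resnik normalized by the terms' own ICs; 0 when both ICs are 0."""
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"term {t!r} not in ontology")
        if t not in icmap:
            raise ValueError(f"term {t!r} has undefined IC")
    denom = icmap[t1] + icmap[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * resnik(t1, t2, dag, icmap) / denom


def _svalues(dag: OntologyDAG, term: str, w: float) -> dict[str, float]:
    """Wang semantic values of all ancestors-or-self of ``term``.

    S(term) = 1; S(a) = w · max over children c of a on an upward path
    from term of S(c).  Computed by relaxing in topological order of
    the ancestor subgraph (child → parent edges).
    """
    anc = dag.ancestors_or_self(term)
    sub = dag.graph.subgraph(anc)
    s = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node not in s:
            continue
        for parent in sub.successors(node):
            cand = w * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def wang(t1: str, t2: str, dag: OntologyDAG,
         contribution_factor: float = 0.8) -> float:
    """Wang structural similarity in (0, 1] for terms sharing any ancestor."""
    if not 0.0 < contribution_factor < 1.0:
        raise ValueError("contribution_factor must be in (0, 1)")
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"term {t!r} not in ontology")
    s1 = _svalues(dag, t1, contribution_factor)
    s2 = _svalues(dag, t2, contribution_factor)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    overlap = sum(s1[a] + s2[a] for a in common)
    return overlap / (sum(s1.values()) + sum(s2.values()))


def bma_similarity(a1: Iterable[str], a2: Iterable[str],
                   termsim: TermSim) -> float:
    """Best-match-average similarity of two term sets, symmetrized.

    Directional score: mean over terms of one set of the best term
    similarity to the other set; the result averages both directions.
    """
    a1, a2 = list(dict.fromkeys(a1)), list(dict.fromkeys(a2))
    if not a1 or not a2:
        raise ValueError("annotation sets must be nonempty")

    def directional(src: list[str], dst: list[str]) -> float:
        return sum(max(termsim(s, t) for t in dst) for s in src) / len(src)

    return 0.5 * directional(a1, a2) + 0.5 * directional(a2, a1)
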