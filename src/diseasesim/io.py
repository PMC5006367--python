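"""Readers and writers for every on-disk artifact.

All tabular files are tab-separated; lines starting with ``#`` are
comments.  Gene and disease identifiers are opaque strings compared
case-sensitively — no identifier mapping is performed here.  Ontologies
use the OBO 1.2 dialect (parsed with :mod:`obonet`), corpora are JSON
lines, one abstract per record.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import obonet

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError", "OntologyDAG", "BenchmarkSet", "SimilarityTable",
    "canonical_pair", "read_obo", "write_obo", "read_network",
    "read_gene_disease", "read_corpus", "read_benchmark",
    "read_similarity", "write_similarity",
]


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically sorted identifier pair.

    Every similarity table and benchmark set keys pairs this way, which
    enforces symmetry by construction.
    """
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

@dataclass
class OntologyDAG:
    """A disease/phenotype ontology restricted to non-obsolete terms.

    ``graph`` is a directed graph with one edge per IS_A relationship,
    oriented child → parent.  ``root_id`` is the unique parentless term,
    or ``None`` when the file has several roots.
    """

    terms: dict[str, dict]          # term-id -> {"name": str, "synonyms": [str]}
    graph: nx.DiGraph               # child -> parent, is_a only
    root_id: str | None = None

    def __post_init__(self) -> None:
        for child, parent in self.graph.edges():
            if child not in self.terms or parent not in self.terms:
                raise ValueError(
                    f"IS_A edge ({child}, {parent}) references unknown term"
                )
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"IS_A relationships contain a cycle: {cycle}")

    # -- traversal helpers used by the semantic and DSN modules ------------

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors_or_self(self, term: str) -> set[str]:
        """The term plus every term reachable by following IS_A upward."""
        if term not in self.terms:
            raise KeyError(term)
        out = {term}
        if term in self.graph:
            out |= nx.descendants(self.graph, term)  # edges point upward
        return out

    def descendants_or_self(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        out = {term}
        if term in self.graph:
            out |= nx.ancestors(self.graph, term)
        return out

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _extract_synonym(raw: str) -> str:
    m = _SYNONYM_RE.match(raw.strip())
    return m.group(1) if m else raw.strip()


def _prevalidate_obo(path: str) -> None:
    """Light line-level scan so malformed stanzas fail with a line number."""
    in_stanza = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("[") :
                if not stripped.endswith("]"):
                    raise ParseError(
                        f"{path}:{lineno}: malformed stanza header {stripped!r}"
                    )
                in_stanza = True
                continue
            if in_stanza and ":" not in stripped:
                raise ParseError(
                    f"{path}:{lineno}: expected 'tag: value' line, got {stripped!r}"
                )


def read_obo(path: str) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into a DAG of non-obsolete terms.

    Obsolete terms are dropped together with any edge touching them.
    Only IS_A relationships are retained; other relationship types are
    ignored.  A cyclic IS_A structure raises :class:`ValueError`.
    """
    _prevalidate_obo(path)
    try:
        g = obonet.read_obo(path, ignore_obsolete=True)
    except ValueError as exc:  # pragma: no cover - obonet internal message
        raise ParseError(f"{path}: {exc}") from exc

    terms: dict[str, dict] = {}
    for node, data in g.nodes(data=True):
        terms[node] = {
            "name": data.get("name", ""),
            "synonyms": [_extract_synonym(s) for s in data.get("synonym", [])],
        }
    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a" and child in terms and parent in terms:
            dag.add_edge(child, parent)

    roots = [t for t in terms if dag.out_degree(t) == 0]
    root_id = roots[0] if len(roots) == 1 else None
    if root_id is None:
        logger.warning("ontology %s has %d roots; root_id left unset",
                       path, len(roots))
    return OntologyDAG(terms=terms, graph=dag, root_id=root_id)


def write_obo(dag: OntologyDAG, path: str) -> None:
    """Serialize a DAG back to OBO 1.2 (inverse of :func:`read_obo`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: diseasesim\n")
        for term in sorted(dag.terms):
            info = dag.terms[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {info['name']}\n")
            for syn in info["synonyms"]:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.terms[parent]['name']}\n")


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def _data_rows(path: str, n_cols: int) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def read_network(path: str) -> InteractionNetwork:
    """Read an undirected edge list into a simple interaction network.

    Duplicate edges (in either orientation) are collapsed; self-loops
    are dropped with a warning, matching RWR's simple-graph assumption.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_self = 0
    for lineno, (a, b) in _data_rows(path, 2):
        if a == b:
            n_self += 1
            logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
            continue
        nodes.add(a)
        nodes.add(b)
        edges.add(canonical_pair(a, b))
    return InteractionNetwork.from_edges(sorted(edges), nodes=sorted(nodes))


def read_gene_disease(path: str) -> dict[str, set[str]]:
    """Read (disease-id, gene-id) rows into a disease → gene-set map."""
    assoc: dict[str, set[str]] = {}
    for _, (disease, gene) in _data_rows(path, 2):
        assoc.setdefault(disease, set()).add(gene)
    if not assoc:
        logger.warning("%s: no gene-disease associations found", path)
    return assoc


def read_corpus(path: str) -> dict[str, list[str]]:
    """Read a JSON-lines corpus into per-disease abstract lists.

    Each record is ``{"disease": id, "text": str, "pmid": optional}``.
    Input order of abstracts is preserved per disease; empty texts are
    retained (they simply score zero relevance downstream).
    """
    corpus: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for idx, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: record {idx}: invalid JSON: {exc}")
            if "disease" not in rec:
                raise ParseError(f"{path}: record {idx}: missing 'disease' field")
            if "text" not in rec:
                raise ParseError(f"{path}: record {idx}: missing 'text' field")
            corpus.setdefault(rec["disease"], []).append(rec["text"])
    return corpus


# ---------------------------------------------------------------------------
# Benchmark pairs
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkSet:
    """Unordered positive disease pairs used as ROC ground truth."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cleaned = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"benchmark pair ({a}, {b}) is degenerate")
            cleaned.add(canonical_pair(a, b))
        self.pairs = cleaned

    @property
    def diseases(self) -> set[str]:
        return {d for pair in self.pairs for d in pair}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def read_benchmark(path: str, vocabulary: Iterable[str] | None = None) -> BenchmarkSet:
    """Read (disease1, disease2) positive pairs.

    When ``vocabulary`` is given, every identifier must be a member —
    benchmark diseases are required to be ontology terms.
    """
    vocab = set(vocabulary) if vocabulary is not None else None
    pairs: set[tuple[str, str]] = set()
    for lineno, (a, b) in _data_rows(path, 2):
        if vocab is not None:
            for d in (a, b):
                if d not in vocab:
                    raise ParseError(
                        f"{path}:{lineno}: disease {d!r} not in vocabulary"
                    )
        pairs.add(canonical_pair(a, b))
    return BenchmarkSet(pairs=pairs)


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------

class SimilarityTable:
    """Symmetric pairwise disease similarities keyed by canonical pairs."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), score in entries.items():
                self.set(a, b, score)

    def set(self, a: str, b: str, score: float) -> None:
        score = float(score)
        if not math.isfinite(score):
            raise ValueError(f"non-finite similarity for ({a}, {b}): {score}")
        self._entries[canonical_pair(a, b)] = score

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._entries.get(canonical_pair(a, b), default)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self._entries[canonical_pair(*pair)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._entries.items())

    def scores(self) -> list[float]:
        return list(self._entries.values())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SimilarityTable)
                and self._entries == other._entries)


def write_similarity(table: SimilarityTable, path: str) -> None:
    """Write a similarity table as TSV with canonical pair ordering.

    Scores use ``repr`` (shortest round-trip float form), so
    :func:`read_similarity` reproduces the table exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#disease1\tdisease2\tscore\n")
        for (a, b), score in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{score!r}\n")


def read_similarity(path: str) -> SimilarityTable:
    """Inverse of :func:`write_similarity`."""
    table = SimilarityTable()
    for lineno, fields in _data_rows(path, 3):
        a, b, raw = fields
        try:
            score = float(raw)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw!r}")
        table.set(a, b, score)
    return table
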