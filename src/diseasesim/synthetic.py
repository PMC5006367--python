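"""Synthetic study generator: aligned network, associations and corpus.

The generator emulates the five inputs the pipeline consumes, with a
planted community structure that couples them:

* genes live in modules; the interaction network is a stochastic block
  model (dense within modules, sparse between);
* each disease has a home module and draws most of its associated
  genes from it (``module_purity``);
* topics are aligned one-to-one with modules; each disease's abstracts
  mix words from its home topic with background vocabulary
  (``topic_purity``);
* the benchmark's positive pairs are same-module disease pairs, so a
  similarity method recovering the planted structure separates them
  from random pairs.

Words are pseudo-words built from a vowel-free consonant alphabet, so
stemming leaves them untouched and topic vocabularies stay disjoint.
All sampling derives from integer-entropy seed sequences, making every
artifact byte-reproducible for a given scenario seed across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .io import BenchmarkSet, OntologyDAG, canonical_pair
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario", "ScenarioData", "gene_ids", "disease_ids",
    "gene_module", "disease_module", "generate_network",
    "generate_associations", "generate_corpus", "generate_benchmark",
    "generate_ontology", "generate_scenario", "write_fixtures",
]

# vowel-free, s-free alphabet: Porter stemming is the identity on these
_WORD_ALPHABET = "bcdfghjklmnpqrtvwxz"

# per-component entropy codes for seed derivation
_SEED_NETWORK = 0
_SEED_ASSOC = 1
_SEED_CORPUS = 2
_SEED_BENCH = 3
_SEED_VOCAB = 4


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    The defaults are the package's reference conditions: a 2,000-gene,
    10-module interaction network (within-module edge probability 0.05,
    between 0.002), 60 diseases with 20 genes each drawn 80 % from the
    home module, and a 10-topic corpus of 30 abstracts per disease at
    70 % topic purity, seed 17.
    """

    n_genes: int = 2000
    n_modules: int = 10
    p_within: float = 0.05
    p_between: float = 0.002
    n_diseases: int = 60
    genes_per_disease: int = 20
    module_purity: float = 0.8
    n_topics: int = 10
    words_per_topic: int = 200
    docs_per_disease: int = 30
    topic_purity: float = 0.7
    rng_seed: int = 17
    # plumbing beyond the planted-structure parameters
    n_benchmark_pairs: int = 40
    words_per_abstract: int = 80
    n_background_words: int = 500
    background_distribution: str = "uniform"   # or "zipf"

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "module_purity", "topic_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_modules", "n_diseases",
                     "genes_per_disease", "n_topics", "words_per_topic",
                     "docs_per_disease", "words_per_abstract"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.background_distribution not in ("uniform", "zipf"):
            raise ValueError("background_distribution must be uniform|zipf")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, rng_seed=seed)


def _rng(scenario: SyntheticScenario, code: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(scenario.rng_seed), code))
    )


def gene_ids(scenario: SyntheticScenario) -> list[str]:
    return [f"G{i:05d}" for i in range(scenario.n_genes)]


def disease_ids(scenario: SyntheticScenario) -> list[str]:
    return [f"SYND:{i:04d}" for i in range(scenario.n_diseases)]


def gene_module(scenario: SyntheticScenario) -> np.ndarray:
    """Module index of every gene (contiguous, near-equal blocks)."""
    return (np.arange(scenario.n_genes) * scenario.n_modules
            // scenario.n_genes)


def disease_module(scenario: SyntheticScenario) -> dict[str, int]:
    """Home module of every disease (round-robin assignment)."""
    return {d: i % scenario.n_modules
            for i, d in enumerate(disease_ids(scenario))}


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(scenario: SyntheticScenario) -> InteractionNetwork:
    """Stochastic-block-model interaction network.

    Genes that draw no edge are absent from the network, which exercises
    the off-network cases of functional relevance downstream.
    """
    rng = _rng(scenario, _SEED_NETWORK)
    genes = gene_ids(scenario)
    modules = gene_module(scenario)
    iu, ju = np.triu_indices(scenario.n_genes, k=1)
    probs = np.where(modules[iu] == modules[ju],
                     scenario.p_within, scenario.p_between)
    mask = rng.random(probs.size) < probs
    edges = [(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])]
    return InteractionNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# Gene–disease associations
# ---------------------------------------------------------------------------

def generate_associations(scenario: SyntheticScenario) -> dict[str, set[str]]:
    """Gene sets per disease: home-module draws mixed with uniform draws.

    ``round(module_purity · genes_per_disease)`` genes come from the
    home module without replacement; the remainder is uniform over the
    rest of the genome, so purity 0 recovers a fully uniform draw.
    """
    rng = _rng(scenario, _SEED_ASSOC)
    genes = np.array(gene_ids(scenario))
    modules = gene_module(scenario)
    homes = disease_module(scenario)
    assoc: dict[str, set[str]] = {}
    for disease in disease_ids(scenario):
        m = homes[disease]
        home_pool = np.flatnonzero(modules == m)
        n_home = round(scenario.module_purity * scenario.genes_per_disease)
        if n_home > home_pool.size:
            raise ValueError(
                f"module {m} has {home_pool.size} genes but purity "
                f"{scenario.module_purity} requires {n_home}"
            )
        chosen = list(rng.choice(home_pool, size=n_home, replace=False))
        rest = np.setdiff1d(np.arange(scenario.n_genes), np.array(chosen,
                                                                  dtype=int))
        n_rest = scenario.genes_per_disease - n_home
        if n_rest:
            chosen += list(rng.choice(rest, size=n_rest, replace=False))
        assoc[disease] = {genes[i] for i in chosen}
    return assoc


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def _pseudo_words(rng: np.random.Generator, n: int, length: int,
                  taken: set[str]) -> list[str]:
    words: list[str] = []
    alphabet = np.array(list(_WORD_ALPHABET))
    while len(words) < n:
        draw = rng.integers(0, len(alphabet), size=(n, length))
        for row in draw:
            w = "".join(alphabet[row])
            if w not in taken:
                taken.add(w)
                words.append(w)
                if len(words) == n:
                    break
    return words


def topic_vocabularies(scenario: SyntheticScenario) -> tuple[list[list[str]], list[str]]:
    """Disjoint per-topic word lists plus the background vocabulary."""
    rng = _rng(scenario, _SEED_VOCAB)
    taken: set[str] = set()
    topics = [
        _pseudo_words(rng, scenario.words_per_topic, 7, taken)
        for _ in range(scenario.n_topics)
    ]
    background = _pseudo_words(rng, scenario.n_background_words, 7, taken)
    return topics, background


def generate_corpus(scenario: SyntheticScenario) -> dict[str, list[str]]:
    """Per-disease abstracts mixing home-topic and background words."""
    rng = _rng(scenario, _SEED_CORPUS)
    topics, background = topic_vocabularies(scenario)
    bg = np.array(background)
    if scenario.background_distribution == "zipf":
        ranks = np.arange(1, bg.size + 1, dtype=float)
        bg_probs = (1.0 / ranks) / (1.0 / ranks).sum()
    else:
        bg_probs = None
    homes = disease_module(scenario)
    corpus: dict[str, list[str]] = {}
    for disease in disease_ids(scenario):
        topic = np.array(topics[homes[disease] % scenario.n_topics])
        abstracts = []
        for _ in range(scenario.docs_per_disease):
            L = scenario.words_per_abstract
            from_topic = rng.random(L) < scenario.topic_purity
            words = np.where(
                from_topic,
                topic[rng.integers(0, topic.size, size=L)],
                bg[rng.choice(bg.size, size=L, p=bg_probs)],
            )
            abstracts.append(" ".join(words))
        corpus[disease] = abstracts
    return corpus


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def generate_benchmark(scenario: SyntheticScenario) -> tuple[BenchmarkSet, list[tuple[str, str]]]:
    """Positive same-module pairs plus the eligible random-pair pool."""
    rng = _rng(scenario, _SEED_BENCH)
    homes = disease_module(scenario)
    ids = disease_ids(scenario)
    same_module = sorted(
        canonical_pair(a, b)
        for i, a in enumerate(ids) for b in ids[i + 1:]
        if homes[a] == homes[b]
    )
    modules_with_one = [
        m for m in range(scenario.n_modules)
        if sum(1 for d in ids if homes[d] == m) < 2
    ]
    for m in modules_with_one:
        logger.warning("module %d has fewer than 2 diseases; "
                       "it contributes no positive pairs", m)
    n = scenario.n_benchmark_pairs
    if n > len(same_module):
        raise ValueError(
            f"requested {n} benchmark pairs but only {len(same_module)} "
            f"same-module pairs exist"
        )
    idx = rng.choice(len(same_module), size=n, replace=False)
    positives = {same_module[i] for i in idx}
    pool = sorted(
        canonical_pair(a, b)
        for i, a in enumerate(ids) for b in ids[i + 1:]
        if canonical_pair(a, b) not in positives
    )
    return BenchmarkSet(pairs=positives), pool


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

ROOT_TERM = "SYND:ROOT"


def generate_ontology(scenario: SyntheticScenario) -> OntologyDAG:
    """DO-like DAG: root → one category per module → disease terms."""
    terms: dict[str, dict] = {
        ROOT_TERM: {"name": "synthetic disease root", "synonyms": []}
    }
    graph = nx.DiGraph()
    graph.add_node(ROOT_TERM)
    homes = disease_module(scenario)
    for m in range(scenario.n_modules):
        cat = f"SYND:C{m:02d}"
        terms[cat] = {"name": f"category {m} disease",
                      "synonyms": [f"module {m} disorder"]}
        graph.add_edge(cat, ROOT_TERM)
    for disease in disease_ids(scenario):
        terms[disease] = {
            "name": f"synthetic disease {disease.split(':')[1]}",
            "synonyms": [f"synthetic disorder {disease.split(':')[1]}"],
        }
        graph.add_edge(disease, f"SYND:C{homes[disease]:02d}")
    return OntologyDAG(terms=terms, graph=graph, root_id=ROOT_TERM)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class ScenarioData:
    """Everything one synthetic study produces."""

    scenario: SyntheticScenario
    network: InteractionNetwork
    gene_disease: dict[str, set[str]]
    disease_module: dict[str, int]
    corpus: dict[str, list[str]]
    benchmark: BenchmarkSet
    random_pool: list[tuple[str, str]] = field(default_factory=list)
    ontology: OntologyDAG | None = None


def generate_scenario(scenario: SyntheticScenario | None = None) -> ScenarioData:
    """Generate all five artifacts of one scenario."""
    scenario = scenario or SyntheticScenario()
    benchmark, pool = generate_benchmark(scenario)
    return ScenarioData(
        scenario=scenario,
        network=generate_network(scenario),
        gene_disease=generate_associations(scenario),
        disease_module=disease_module(scenario),
        corpus=generate_corpus(scenario),
        benchmark=benchmark,
        random_pool=pool,
        ontology=generate_ontology(scenario),
    )


def write_fixtures(data: ScenarioData, out_dir: str) -> dict[str, str]:
    """Write every artifact in its on-disk dialect; returns the paths."""
    import json
    import os

    from .io import write_obo

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ontology": os.path.join(out_dir, "ontology.obo"),
        "network": os.path.join(out_dir, "network.tsv"),
        "associations": os.path.join(out_dir, "associations.tsv"),
        "corpus": os.path.join(out_dir, "corpus.jsonl"),
        "benchmark": os.path.join(out_dir, "benchmark.tsv"),
    }
    if data.ontology is not None:
        write_obo(data.ontology, paths["ontology"])
    net = data.network.to_networkx()
    with open(paths["network"], "w", encoding="utf-8") as fh:
        fh.write("#gene1\tgene2\n")
        for a, b in sorted(canonical_pair(a, b) for a, b in net.edges()):
            fh.write(f"{a}\t{b}\n")
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        fh.write("#disease\tgene\n")
        for disease in sorted(data.gene_disease):
            for gene in sorted(data.gene_disease[disease]):
                fh.write(f"{disease}\t{gene}\n")
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for disease in sorted(data.corpus):
            for text in data.corpus[disease]:
                fh.write(json.dumps({"disease": disease, "text": text},
                                    sort_keys=True) + "\n")
    with open(paths["benchmark"], "w", encoding="utf-8") as fh:
        fh.write("#disease1\tdisease2\n")
        for a, b in sorted(data.benchmark.pairs):
            fh.write(f"{a}\t{b}\n")
    return paths
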