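"""Literature-based disease similarity (MedSim).

Pipeline: per disease, rank the retrieved abstracts by a relevance score
(sum over informative words of document frequency × in-abstract
occurrence count), keep the top ``k`` (100 by default) and merge them
into one document; build a pruned bag-of-words vocabulary over the
merged documents; weight with TF-IDF; MedSim of two diseases is the
cosine of their vectors.

Tokenization lowercases, keeps alphabetic tokens only and Porter-stems
them.  Informative words for the relevance score are those whose
document frequency within the disease's own abstract set exceeds a
threshold (0.005 by default); an optional noun filter restricts them
further — by default no part-of-speech filtering is applied, and a
caller with a POS tagger can pass any predicate ``word -> bool``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from . import _porter

logger = logging.getLogger(__name__)

__all__ = [
    "tokenize", "WordStats", "word_stats", "abstract_relevance",
    "DiseaseDocument", "select_top_abstracts", "VectorSpaceModel",
    "build_vocabulary", "vectorize_corpus", "medsim",
]

_WORD_RE = re.compile(r"[a-z]+")

NounFilter = Callable[[str], bool]


def tokenize(text: str) -> list[str]:
    """Lowercase, keep alphabetic tokens, Porter-stem; order preserved."""
    return [_porter.stem(tok) for tok in _WORD_RE.findall(text.lower())]


@dataclass
class WordStats:
    """Word statistics over one disease's abstract set.

    ``doc_freq`` maps a stem to the fraction of the disease's abstracts
    containing it; ``occurrences[i]`` counts stems within abstract ``i``.
    """

    doc_freq: dict[str, float]
    occurrences: list[Counter]

    @property
    def n_abstracts(self) -> int:
        return len(self.occurrences)


def word_stats(abstract_tokens: Sequence[Sequence[str]]) -> WordStats:
    """Document frequencies and per-abstract counts for one disease."""
    counts = [Counter(tokens) for tokens in abstract_tokens]
    n = len(counts)
    df: Counter = Counter()
    for c in counts:
        df.update(c.keys())
    doc_freq = {w: k / n for w, k in df.items()} if n else {}
    return WordStats(doc_freq=doc_freq, occurrences=counts)


def abstract_relevance(abstract_tokens: Sequence[str], stats: WordStats,
                       df_threshold: float = 0.005,
                       noun_filter: NounFilter | None = None) -> float:
    """Relevance of one abstract to its disease.

    Sum over informative words (document frequency above the threshold,
    optionally noun-filtered) of document frequency × occurrence count
    in this abstract.  Linear in the occurrence counts.
    """
    counts = Counter(abstract_tokens)
    score = 0.0
    for word, n_occ in counts.items():
        df = stats.doc_freq.get(word, 0.0)
        if df <= df_threshold:
            continue
        if noun_filter is not None and not noun_filter(word):
            continue
        score += df * n_occ
    return score


@dataclass
class DiseaseDocument:
    """Merged document of a disease's most relevant abstracts."""

    disease_id: str
    merged_text: str
    selected_count: int
    empty: bool = field(default=False)


def select_top_abstracts(disease_id: str, abstracts: Sequence[str],
                         k: int = 100, df_threshold: float = 0.005,
                         noun_filter: NounFilter | None = None) -> DiseaseDocument:
    """Rank abstracts by relevance, merge the top ``k`` into one document.

    Diseases with fewer than ``k`` abstracts keep all of them.  Ties are
    broken by input order (stable sort).  Zero abstracts give an empty,
    flagged document.
    """
    if not abstracts:
        logger.warning("disease %s has no abstracts; empty document", disease_id)
        return DiseaseDocument(disease_id, "", 0, empty=True)
    token_lists = [tokenize(text) for text in abstracts]
    stats = word_stats(token_lists)
    scores = [
        abstract_relevance(toks, stats, df_threshold, noun_filter)
        for toks in token_lists
    ]
    order = sorted(range(len(abstracts)), key=lambda i: -scores[i])
    chosen = sorted(order[:k])  # keep original order inside the document
    merged = "\n".join(abstracts[i] for i in chosen)
    return DiseaseDocument(disease_id, merged, len(chosen))


@dataclass
class VectorSpaceModel:
    """Pruned vocabulary with per-disease TF-IDF vectors.

    Weights are raw term count × smoothed inverse document frequency
    ``ln((1 + N) / (1 + df)) + 1``, L2-normalized, so cosine similarity
    reduces to a dot product.
    """

    vocabulary: list[str]
    idf: np.ndarray
    vectors: dict[str, sp.csr_matrix]

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)


def build_vocabulary(documents: Sequence[DiseaseDocument],
                     max_df: float = 0.60,
                     min_df: int = 4) -> VectorSpaceModel:
    """TF-IDF model over merged disease documents.

    Words in more than ``max_df`` (fraction) of the documents or in
    fewer than ``min_df`` documents are pruned — overly common or rare
    words carry no discriminating information.
    """
    if not documents:
        raise ValueError("no documents")
    if all(not d.merged_text.strip() for d in documents):
        raise ValueError("all documents are empty")
    vec = TfidfVectorizer(
        analyzer=tokenize, max_df=max_df, min_df=min_df,
        norm="l2", smooth_idf=True, sublinear_tf=False,
    )
    try:
        matrix = vec.fit_transform([d.merged_text for d in documents])
    except ValueError as exc:
        raise ValueError(
            "vocabulary is empty after pruning; relax max_df/min_df"
        ) from exc
    vocab = vec.get_feature_names_out().tolist()
    vectors = {
        doc.disease_id: matrix.getrow(i).tocsr()
        for i, doc in enumerate(documents)
    }
    return VectorSpaceModel(vocabulary=vocab, idf=vec.idf_, vectors=vectors)


def vectorize_corpus(corpus: Mapping[str, Sequence[str]],
                     top_k: int = 100, df_threshold: float = 0.005,
                     max_df: float = 0.60, min_df: int = 4,
                     noun_filter: NounFilter | None = None) -> VectorSpaceModel:
    """Full literature pipeline: select, merge, prune, vectorize."""
    documents = [
        select_top_abstracts(d, corpus[d], k=top_k,
                             df_threshold=df_threshold,
                             noun_filter=noun_filter)
        for d in sorted(corpus)
    ]
    return build_vocabulary(documents, max_df=max_df, min_df=min_df)


def medsim(vsm: VectorSpaceModel, d1: str, d2: str) -> float:
    """Cosine similarity of two diseases' TF-IDF vectors, in [0, 1].

    Zero when either vector is all-zero (disease with no surviving
    vocabulary words).  Raises ``KeyError`` for unknown diseases.
    """
    v1 = vsm.vectors[d1]
    v2 = vsm.vectors[d2]
    # rows are L2-normalized by construction; zero rows stay zero
    sim = float(v1.multiply(v2).sum())
    return min(max(sim, 0.0), 1.0)
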