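"""Tokenization, abstract relevance, vocabulary pruning and MedSim."""

import math

import numpy as np
import pytest

from diseasesim import literature as lit
from diseasesim._porter import stem

# frozen reference vectors of the classic suffix-stripping algorithm
PORTER_VECTORS = {
    "caresses": "caress", "ponies": "poni", "ties": "ti",
    "caress": "caress", "cats": "cat", "feed": "feed", "agreed": "agre",
    "plastered": "plaster", "bled": "bled", "motoring": "motor",
    "sing": "sing", "conflated": "conflat", "troubling": "troubl",
    "sized": "size", "hopping": "hop", "tanned": "tan", "falling": "fall",
    "hissing": "hiss", "fizzed": "fizz", "failing": "fail",
    "filing": "file", "happy": "happi", "sky": "sky",
    "relational": "relat", "conditional": "condit", "rational": "ration",
    "generalization": "gener", "oscillators": "oscil", "cells": "cell",
    "dividing": "divid", "adjustment": "adjust",
    "replacement": "replac", "hesitancy": "hesit",
    "controlling": "control", "rolling": "roll",
}


class TestTokenize:
    @pytest.mark.parametrize("word,expected", sorted(PORTER_VECTORS.items()))
    def test_stemmer_reference_vectors(self, word, expected):
        assert stem(word) == expected

    def test_drops_non_alphabetic_and_stems(self):
        assert lit.tokenize("Cells 123 dividing!") == ["cell", "divid"]

    def test_empty_text(self):
        assert lit.tokenize("") == []

    def test_stable_on_stem_closed_vocabulary(self):
        tokens = lit.tokenize("walk cell tumor growth of net")
        assert lit.tokenize(" ".join(tokens)) == tokens


class TestAbstractRelevance:
    def toy_stats(self):
        # 3 abstracts over a closed vocabulary; df and counts tabulated
        abstracts = [
            ["tumor", "growth", "tumor"],
            ["tumor", "cell"],
            ["cell", "growth", "cell", "cell"],
        ]
        return abstracts, lit.word_stats(abstracts)

    def test_document_frequencies(self):
        _, stats = self.toy_stats()
        assert stats.doc_freq == {
            "tumor": 2 / 3, "growth": 2 / 3, "cell": 2 / 3,
        }

    def test_hand_summed_relevance(self):
        abstracts, stats = self.toy_stats()
        # abstract 0: tumor df 2/3 × of 2 + growth df 2/3 × of 1 = 2
        assert lit.abstract_relevance(abstracts[0], stats) == pytest.approx(2.0)
        # abstract 2: cell 2/3 × 3 + growth 2/3 × 1 = 8/3
        assert lit.abstract_relevance(abstracts[2], stats) == pytest.approx(8 / 3)

    def test_no_shared_informative_word_scores_zero(self):
        _, stats = self.toy_stats()
        assert lit.abstract_relevance(["unseen"], stats) == 0.0

    def test_linear_in_occurrence_counts(self):
        abstracts, stats = self.toy_stats()
        doubled = abstracts[0] + abstracts[0]
        assert lit.abstract_relevance(doubled, stats) == pytest.approx(
            2 * lit.abstract_relevance(abstracts[0], stats)
        )

    def test_df_threshold_excludes_rare_words(self):
        abstracts, stats = self.toy_stats()
        high = lit.abstract_relevance(abstracts[0], stats, df_threshold=0.9)
        assert high == 0.0

    def test_noun_filter_is_pluggable(self):
        abstracts, stats = self.toy_stats()
        only_tumor = lit.abstract_relevance(
            abstracts[0], stats, noun_filter=lambda w: w == "tumor"
        )
        assert only_tumor == pytest.approx(2 / 3 * 2)


class TestSelectTopAbstracts:
    def test_fewer_than_k_keeps_all(self):
        abstracts = [f"word{i} tumor" for i in range(40)]
        doc = lit.select_top_abstracts("d", abstracts, k=100)
        assert doc.selected_count == 40

    def test_more_than_k_keeps_exactly_k(self):
        abstracts = ["tumor cell growth"] * 150
        doc = lit.select_top_abstracts("d", abstracts, k=100)
        assert doc.selected_count == 100

    def test_ties_break_by_input_order(self):
        abstracts = ["aaa bbb", "aaa bbb", "ccc aaa aaa"]
        doc = lit.select_top_abstracts("d", abstracts, k=1, df_threshold=0.0)
        # df(aaa)=1, df(bbb)=2/3, df(ccc)=1/3; a2 scores 2 + 1/3,
        # a0/a1 score 1 + 2/3 → a2 wins outright
        assert doc.merged_text == "ccc aaa aaa"
        doc2 = lit.select_top_abstracts("d", ["x y", "x y"], k=1,
                                        df_threshold=0.0)
        assert doc2.merged_text == "x y"  # first of equals

    def test_zero_abstracts_flagged_empty(self):
        doc = lit.select_top_abstracts("d", [])
        assert doc.empty and doc.selected_count == 0 and doc.merged_text == ""


def docs(texts):
    return [lit.DiseaseDocument(f"d{i}", t, 1) for i, t in enumerate(texts)]


class TestBuildVocabulary:
    def test_overly_common_words_pruned(self):
        # "common" in 7 of 10 documents (> 60 %) must disappear
        texts = [f"common unique{i}" for i in range(7)]
        texts += [f"rare{i} filler{i % 2}" for i in range(3)]
        vsm = lit.build_vocabulary(docs(texts), max_df=0.60, min_df=1)
        assert "common" not in vsm.vocabulary

    def test_min_df_boundary_keeps_exactly_four(self):
        texts = (["kept keptb"] * 4 + ["gone"] * 3
                 + ["padding%d" % i for i in range(3)])
        vsm = lit.build_vocabulary(docs(texts), max_df=0.60, min_df=4)
        assert "kept" in vsm.vocabulary
        assert "gone" not in vsm.vocabulary

    def test_surviving_vocabulary_equals_brute_force(self):
        rng = np.random.default_rng(2)
        words = ["cell", "tumor", "growth", "gene", "net", "path", "walk"]
        texts = [
            " ".join(rng.choice(words, size=6)) for _ in range(5)
        ]
        max_df, min_df = 0.60, 2
        vsm = lit.build_vocabulary(docs(texts), max_df=max_df, min_df=min_df)
        token_sets = [set(lit.tokenize(t)) for t in texts]
        expected = {
            w for w in set().union(*token_sets)
            if min_df <= sum(w in s for s in token_sets) <= max_df * len(texts)
        }
        assert set(vsm.vocabulary) == expected

    def test_empty_vocabulary_suggests_relaxing_thresholds(self):
        with pytest.raises(ValueError, match="max_df"):
            lit.build_vocabulary(docs(["solo"]), max_df=0.6, min_df=4)

    def test_pruning_is_order_independent(self):
        texts = ["cell tumor", "tumor growth", "growth cell", "cell gene"]
        a = lit.build_vocabulary(docs(texts), max_df=0.9, min_df=2)
        b = lit.build_vocabulary(docs(texts[::-1]), max_df=0.9, min_df=2)
        assert set(a.vocabulary) == set(b.vocabulary)


class TestMedSim:
    def build(self, texts, **kw):
        kw.setdefault("max_df", 1.0)
        kw.setdefault("min_df", 1)
        return lit.build_vocabulary(docs(texts), **kw)

    def test_identical_documents_score_one(self):
        vsm = self.build(["tumor cell growth", "tumor cell growth"])
        assert lit.medsim(vsm, "d0", "d1") == pytest.approx(1.0)

    def test_disjoint_vocabulary_scores_zero(self):
        vsm = self.build(["tumor cell", "walk path"])
        assert lit.medsim(vsm, "d0", "d1") == 0.0

    def test_two_disease_three_word_hand_computed_cosine(self):
        # d0: tumor×2 cell×1 ; d1: tumor×1 walk×1
        vsm = self.build(["tumor tumor cell", "tumor walk"])
        n_docs = 2
        idf_shared = math.log((1 + n_docs) / (1 + 2)) + 1      # tumor
        idf_solo = math.log((1 + n_docs) / (1 + 1)) + 1        # cell, walk
        v0 = {"tumor": 2 * idf_shared, "cell": 1 * idf_solo}
        v1 = {"tumor": 1 * idf_shared, "walk": 1 * idf_solo}
        dot = v0["tumor"] * v1["tumor"]
        norm0 = math.hypot(*v0.values())
        norm1 = math.hypot(*v1.values())
        assert lit.medsim(vsm, "d0", "d1") == pytest.approx(
            dot / (norm0 * norm1), abs=1e-12
        )

    def test_self_similarity_is_one(self):
        vsm = self.build(["tumor cell", "walk path"])
        assert lit.medsim(vsm, "d0", "d0") == pytest.approx(1.0)

    def test_symmetry(self):
        vsm = self.build(["tumor tumor cell", "tumor walk path"])
        assert lit.medsim(vsm, "d0", "d1") == lit.medsim(vsm, "d1", "d0")

    def test_verbatim_duplication_leaves_cosine_unchanged(self):
        # raw counts double but L2 normalization cancels the scale
        vsm_a = self.build(["tumor cell", "tumor walk"])
        vsm_b = self.build(["tumor cell tumor cell", "tumor walk"])
        assert lit.medsim(vsm_b, "d0", "d1") == pytest.approx(
            lit.medsim(vsm_a, "d0", "d1"), abs=1e-12
        )

    def test_unknown_disease_raises(self):
        vsm = self.build(["tumor cell"])
        with pytest.raises(KeyError):
            lit.medsim(vsm, "d0", "nope")

    def test_same_topic_diseases_outscore_cross_topic(self, small_data):
        vsm = lit.vectorize_corpus(small_data.corpus, top_k=100, min_df=2)
        homes = small_data.disease_module
        ds = sorted(homes)
        same, cross = [], []
        for i, a in enumerate(ds):
            for b in ds[i + 1:]:
                (same if homes[a] == homes[b] else cross).append(
                    lit.medsim(vsm, a, b)
                )
        assert np.mean(same) > np.mean(cross)
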