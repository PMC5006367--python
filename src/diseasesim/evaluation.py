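"""Fusion, benchmark evaluation and empirical significance.

The evaluation protocol treats a curated benchmark of related disease
pairs as positives and repeatedly drawn random disease pairs (benchmark
pairs excluded) as negatives; each iteration scores both sets with a
similarity method and computes the ROC AUC via the rank (Mann–Whitney)
formulation with half-credit for ties.  Significance of an individual
pair's similarity is its empirical p-value in the all-pairs score
distribution: the fraction of scores at least as large, floored at 1/N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import BenchmarkSet, SimilarityTable, canonical_pair
from .literature import VectorSpaceModel, medsim
from .network import (InteractionNetwork, NetSimParams, RWRResult,
                      _maybe_rwr, _netsim_from_results)

logger = logging.getLogger(__name__)

__all__ = [
    "mednetsim", "sample_random_pairs", "roc_auc", "roc_curve_points",
    "evaluate", "empirical_pvalue", "pvalue_report",
    "EvaluationResult", "PValueReport", "iteration_seed",
    "NetSimScorer", "MedSimScorer", "ProductScorer",
]

PairScorer = Callable[[str, str], float]


def mednetsim(med: float, net: float) -> float:
    """Fused similarity: the product of MedSim and NetSim."""
    if med < 0 or net < 0 or not (np.isfinite(med) and np.isfinite(net)):
        raise ValueError("similarities must be finite and non-negative")
    return med * net


# ---------------------------------------------------------------------------
# Random negative sets
# ---------------------------------------------------------------------------

def _pair_from_code(code: int, m: int) -> tuple[int, int]:
    """Decode an integer in [0, C(m,2)) into an (i < j) index pair."""
    # row i contributes (m - 1 - i) pairs; invert the triangular layout
    i = int(m - 2 - np.floor(
        np.sqrt(-8 * code + 4 * m * (m - 1) - 7) / 2.0 - 0.5
    ))
    j = int(code + i + 1 - m * (m - 1) // 2 + (m - i) * ((m - i) - 1) // 2)
    return i, j


def sample_random_pairs(diseases: Sequence[str], n: int = 700,
                        exclude: BenchmarkSet | None = None,
                        seed: int | np.random.SeedSequence = 0) -> list[tuple[str, str]]:
    """Draw ``n`` distinct unordered disease pairs outside ``exclude``.

    Reproducible for a given seed.  Raises when fewer than ``n``
    eligible pairs exist, reporting the achievable maximum.
    """
    ids = sorted(set(diseases))
    m = len(ids)
    total = m * (m - 1) // 2
    excluded = set()
    if exclude is not None:
        id_set = set(ids)
        excluded = {p for p in exclude.pairs
                    if p[0] in id_set and p[1] in id_set}
    eligible = total - len(excluded)
    if n > eligible:
        raise ValueError(
            f"requested {n} random pairs but only {eligible} eligible "
            f"pairs exist among {m} diseases"
        )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    if n > total // 2:
        # dense regime: shuffle the full enumeration
        codes = rng.permutation(total)
        for code in codes:
            i, j = _pair_from_code(int(code), m)
            pair = (ids[i], ids[j])
            if pair in excluded:
                continue
            chosen.append(pair)
            if len(chosen) == n:
                break
    else:
        # sparse regime: rejection sampling on pair codes
        while len(chosen) < n:
            for code in rng.integers(0, total, size=2 * (n - len(chosen))):
                i, j = _pair_from_code(int(code), m)
                pair = (ids[i], ids[j])
                if pair in excluded or pair in seen:
                    continue
                seen.add(pair)
                chosen.append(pair)
                if len(chosen) == n:
                    break
    return chosen


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """AUC by the rank formulation, half-credit for ties.

    Equals the probability that a random positive outscores a random
    negative: [#(p > n) + ½·#(p = n)] / (|P|·|N|).
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positives and negatives must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float(
        (rank_sum - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    )


def roc_curve_points(positives: Sequence[float],
                     negatives: Sequence[float]) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the ROC curve, descending score threshold."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positives and negatives must be nonempty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


# ---------------------------------------------------------------------------
# Repeated-random-set evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-iteration AUCs of a benchmark-vs-random evaluation."""

    auc_per_iteration: list[float]
    mean_auc: float
    positive_scores: list[float]
    negative_scores: list[float]
    iterations: int
    rng_seed: int

    @property
    def auc_std_error(self) -> float:
        aucs = np.asarray(self.auc_per_iteration)
        if aucs.size < 2:
            return float("nan")
        return float(aucs.std(ddof=1) / np.sqrt(aucs.size))


def iteration_seed(master_seed: int, iteration: int) -> np.random.SeedSequence:
    """Fixed counter scheme: any iteration is reproducible in isolation."""
    return np.random.SeedSequence(entropy=(int(master_seed), int(iteration)))


def evaluate(method: PairScorer, benchmark: BenchmarkSet,
             diseases: Sequence[str], iterations: int = 50,
             n_random: int = 700, seed: int = 0) -> EvaluationResult:
    """Benchmark-vs-random AUC, averaged over repeated random sets.

    ``diseases`` is the pool negatives are drawn from — callers should
    restrict it to diseases the method can actually score.  Every
    benchmark pair must be scoreable; otherwise the run aborts listing
    the offending diseases.
    """
    if not benchmark.pairs:
        raise ValueError("benchmark set is empty")
    pos_pairs = sorted(benchmark.pairs)
    pos_scores: list[float] = []
    failures: list[tuple[str, str]] = []
    for a, b in pos_pairs:
        try:
            pos_scores.append(float(method(a, b)))
        except (KeyError, ValueError):
            failures.append((a, b))
    if failures:
        raise ValueError(
            f"benchmark pairs not scoreable by the method: {failures}"
        )

    aucs: list[float] = []
    neg_scores: list[float] = []
    for it in range(iterations):
        pairs = sample_random_pairs(
            diseases, n=n_random, exclude=benchmark,
            seed=iteration_seed(seed, it),
        )
        neg_scores = [float(method(a, b)) for a, b in pairs]
        aucs.append(roc_auc(pos_scores, neg_scores))
    return EvaluationResult(
        auc_per_iteration=aucs,
        mean_auc=float(np.mean(aucs)),
        positive_scores=pos_scores,
        negative_scores=neg_scores,
        iterations=iterations,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

def empirical_pvalue(score: float, distribution: Sequence[float]) -> float:
    """Fraction of the all-pairs distribution at least as large as ``score``.

    Floored at 1/N so no p-value is exactly zero; a pair is called
    related when p ≤ 0.05 (the top 5 % of the distribution).
    """
    dist = np.asarray(distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("distribution is empty")
    count = int((dist >= score).sum())
    return max(count, 1) / dist.size


@dataclass
class PValueReport:
    """Per-pair empirical significance for the three measures."""

    pair: tuple[str, str]
    medsim_p: float
    netsim_p: float
    mednetsim_p: float
    related: dict[str, bool]


def pvalue_report(pair: tuple[str, str],
                  med_table: SimilarityTable,
                  net_table: SimilarityTable,
                  fused_table: SimilarityTable,
                  alpha: float = 0.05) -> PValueReport:
    """Empirical p-values of one pair against each all-pairs distribution."""
    a, b = canonical_pair(*pair)
    ps = {}
    for name, table in (("medsim", med_table), ("netsim", net_table),
                        ("mednetsim", fused_table)):
        ps[name] = empirical_pvalue(table[(a, b)], table.scores())
    return PValueReport(
        pair=(a, b),
        medsim_p=ps["medsim"],
        netsim_p=ps["netsim"],
        mednetsim_p=ps["mednetsim"],
        related={name: p <= alpha for name, p in ps.items()},
    )


# ---------------------------------------------------------------------------
# Pair scorers (cache-aware method closures for `evaluate`)
# ---------------------------------------------------------------------------

class NetSimScorer:
    """NetSim pair scorer with one cached RWR solve per disease."""

    def __init__(self, network: InteractionNetwork,
                 gene_disease: Mapping[str, set[str]],
                 params: NetSimParams | None = None):
        self.network = network
        self.gene_disease = {d: frozenset(g) for d, g in gene_disease.items()
                             if g}
        self.params = params or NetSimParams()
        self._cache: dict[str, RWRResult | None] = {}

    def _result(self, disease: str) -> RWRResult | None:
        if disease not in self._cache:
            self._cache[disease] = _maybe_rwr(
                self.network, self.gene_disease[disease], self.params
            )
        return self._cache[disease]

    def __call__(self, d1: str, d2: str) -> float:
        g1 = self.gene_disease[d1]
        g2 = self.gene_disease[d2]
        return _netsim_from_results(
            self.network, g1, g2, self._result(d1), self._result(d2)
        )

    @property
    def diseases(self) -> list[str]:
        return sorted(self.gene_disease)


class MedSimScorer:
    """MedSim pair scorer over a fitted vector-space model."""

    def __init__(self, vsm: VectorSpaceModel):
        self.vsm = vsm

    def __call__(self, d1: str, d2: str) -> float:
        return medsim(self.vsm, d1, d2)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.vsm.vectors)


class ProductScorer:
    """Fused scorer: product of two pair scorers (MedNetSim)."""

    def __init__(self, first: PairScorer, second: PairScorer):
        self.first = first
        self.second = second

    def __call__(self, d1: str, d2: str) -> float:
        return mednetsim(self.first(d1, d2), self.second(d1, d2))


def similarity_table(scorer: PairScorer,
                     pairs: Iterable[tuple[str, str]]) -> SimilarityTable:
    """Score every pair into a symmetric table (skips unscoreable pairs)."""
    table = SimilarityTable()
    skipped = 0
    for a, b in pairs:
        a, b = canonical_pair(a, b)
        if (a, b) in table:
            continue
        try:
            table.set(a, b, scorer(a, b))
        except (KeyError, ValueError):
            skipped += 1
    if skipped:
        logger.warning("similarity_table skipped %d unscoreable pairs", skipped)
    return table
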