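# Methods

## Network-based similarity (NetSim)

The interaction network is an undirected simple graph over opaque gene
identifiers; duplicate, reversed and self-loop edges are removed at read
time, and edges are unweighted. Propagation uses random walk with restart:
the steady state solves `p = r·e + (1 − r)·T·p` with `T = A·D⁻¹` the
column-stochastic transition matrix, so each gene spreads its probability
equally over its neighbors and total mass is conserved (`Σp = Σe`). Columns
of degree-zero nodes are replaced by the restart distribution `e/Σe`, which
preserves conservation instead of silently losing the walker.

The restart vector places 1.0 on every in-network seed gene — taken
literally from the method's definition — and a `normalize_seeds` flag
offers the conventional probability-vector variant (`e/Σe`); the default is
the literal form. The restart probability is not fixed by the method's
definition; the default 0.7 follows the RWR gene-prioritization convention
and is exposed as a parameter. Convergence is declared at L1 residual
≤ 1e-9 or after 1,000 power iterations, whichever first; non-convergence is
flagged on the result, not fatal (with `r = 0.7` the iteration contracts at
rate 0.3 and converges in ~20 steps).

Functional relevance of a gene to a gene set is the gene's steady-state
probability if it is a network node; genes outside the network score 1 when
they belong to the set and 0 otherwise, so diseases whose genes are poorly
covered by the interactome still receive credit for literal gene sharing.
NetSim averages relevance over both directions and needs exactly two RWR
solves per pair; the batch interface (`netsim_matrix`, `NetSimScorer`)
caches one solve per disease. An empty gene set is an error — similarity is
undefined there, which is deliberately distinct from a score of 0.

## Literature-based similarity (MedSim)

Tokenization lowercases, keeps purely alphabetic tokens and stems them with
an in-package implementation of the classic Porter algorithm (verified
against frozen reference vectors in the test suite). Abstract relevance to
a disease is `Σ_W W_df·W_of`: document frequency is computed over that
disease's own abstract set (the statistic is introduced per disease, before
merging), and the informative-word set `W` keeps words with document
frequency above 0.005. Word classes: the definition of `W` restricts to
nouns; no part-of-speech tagger ships with the package, so the default
applies no POS filter and the `noun_filter` argument accepts any
`word → bool` predicate for callers who have a tagger. This is the
documented fallback mode; with topically coherent abstracts the df
threshold does most of the filtering work.

Per disease, the top 100 abstracts by relevance (all of them when fewer
exist) are merged; ties at the cutoff are broken by input order (stable
sort). The vocabulary over merged documents drops words in more than 60 %
of documents or fewer than 4 documents — the overly common and the rare
carry no discriminating signal; no explicit stop-word list is used because
max-df pruning subsumes it. The exact TF-IDF variant is a free choice;
the package uses raw term count × smoothed idf `ln((1+N)/(1+df)) + 1` with
L2 normalization (the mainstream vectorizer default, delegated to
scikit-learn), so cosine similarity is a dot product, duplicating a
document verbatim leaves its similarities unchanged, and MedSim is in
[0, 1] with `medsim(d, d) = 1` for any non-zero vector.

## Fusion and significance

MedNetSim is the product of the two scores, so it is bounded by the smaller
factor and zero whenever either signal is absent. Significance of a pair is
empirical: the fraction of the all-pairs score distribution at least as
large as the pair's score (ties counted as ≥), floored at 1/N; p ≤ 0.05 —
the top 5 % of the distribution — is called related.

## Ontology baselines

Information content is annotation-frequency based: each (entity, term)
annotation instance counts toward the term and all its IS_A ancestors, and
`IC(t) = −ln(count/total)`; terms with zero propagated count have undefined
IC and are excluded from best-match-average sets (logged). A structural
fallback (`descendant-count` IC) serves ontologies without annotations.
Resnik is the IC of the most informative common ancestor, Lin normalizes it
by the terms' own ICs (0 when the denominator is 0), and Wang accumulates
per-ancestor semantic values decaying by a contribution factor of 0.8 per
IS_A edge — the method's published value; IS_A is the only edge type here.
Set similarity is the symmetrized best-match average: the directional form
is biased (a subset always scores 1 toward its superset), so both
directions are averaged.

## Evaluation protocol

Positives are a curated benchmark of related disease pairs; negatives are
`n_random` pairs drawn uniformly without replacement from the eligible
diseases with benchmark pairs excluded. Eligibility is restricted to
diseases the evaluated method can actually score (gene sets for NetSim,
documents for MedSim) — without that restriction unscoreable pairs would
need arbitrary imputation. AUC uses the rank (Mann–Whitney) formulation
with half-credit for ties, making it deterministic and exactly equal to
cross-pair enumeration. The experiment repeats over independent random
sets (50 by default; the desk-scale checks use 10) and reports per-iteration
AUCs and their mean; per-iteration seeds derive from the master seed via a
fixed `(master, iteration)` entropy scheme so any single iteration is
reproducible in isolation.

## Disease similarity network

The DSN keeps the `floor(f·N)` highest-scoring of the `N` scored pairs
(default `f = 0.005`). Floor is used for the cutoff count; ties at the
cutoff are broken by canonical (lexicographic) pair order so the edge set
is deterministic. Nodes are only the diseases incident to a kept edge; each
node carries every top-level category (root children that are ancestors of
the disease — several in a multi-parent DAG) plus a lexicographically first
primary category for single-color rendering.

## Synthetic data: what it emulates and what it does not

The generator plants one shared structure across all data kinds: genes live
in modules (stochastic block model), each disease draws
`round(purity·k)` of its `k` genes from its home module and the rest
uniformly from the genome, topics align one-to-one with modules, and each
abstract mixes home-topic words with background words. Reference
conditions: 2,000 genes, 10 modules, edge probabilities 0.05 within / 0.002
between, 60 diseases × 20 genes at purity 0.8, 10 topics × 200 words, 30
abstracts of 80 words per disease at topic purity 0.7, 500 background
words (uniform by default, Zipf optional), seed 17. The benchmark samples
40 positive pairs from the ~150 same-module pairs, leaving both positives
and the random pool non-degenerate. Words are vowel-free pseudo-words, so
stemming is the identity and topic vocabularies stay exactly disjoint; all
sampling flows through integer-entropy seed sequences, giving bytewise
reproducibility across platforms.

What passing on this fixture shows: the pipeline recovers planted joint
structure from network and text signals, end to end, deterministically.
What it does not show: real MEDLINE language (morphology, synonymy,
polysemy, stop-word load), real interactome topology (degree heavy tails,
hubs, study bias), realistic gene-set size dispersion, or disagreement
between literature and network evidence — module and topic assignments
coincide here by construction, so fusion can only be checked for
non-degradation, not for resolving conflicting signals.

## Numerical choices and degenerate inputs

L1 convergence tolerance 1e-9; AUC and similarity arithmetic in double
precision; similarity tables store finite values only and serialize floats
via `repr` for exact round-trips; canonical (sorted) pair keys enforce
symmetry everywhere. Degenerate cases are explicit: empty gene sets and
empty annotation sets are errors, a disease with zero abstracts yields an
empty flagged document (and zero vector), an all-pruned vocabulary raises
with a suggestion to relax thresholds, and a DSN cutoff that keeps no edge
returns an empty network with a warning.

## Known limitations

Identifiers are opaque strings: no UMLS/DOID or protein-to-gene mapping is
performed, so inputs must arrive pre-mapped. Corpus retrieval is out of
scope — the package consumes already-fetched abstracts. The network is
unweighted; weighted interactomes would need a weighted transition matrix.
POS-based noun filtering requires a user-supplied tagger. Desk-scale AUC
estimates carry the variance of small random sets; the per-iteration AUC
list and standard error are reported so users can scale iterations up.
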