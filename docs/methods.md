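# Methods

This note records the scientific and numerical choices behind `litsim`: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Corpus model and preprocessing

A document is a bibliographic record: id, title, abstract, MeSH descriptor
strings (optionally tagged with their descriptor class), grant ids,
publication year and a reference count. The inclusion filter keeps records
with a non-empty title+abstract, year within a window (default 2004–2008),
at least 5 MeSH terms and at least 5 references; records with an unknown
reference count fail the reference criterion unless it is waived.

Title+abstract tokenization: NFKC normalization (right single quotes mapped
to the ASCII apostrophe), every Unicode punctuation character except the
apostrophe replaced by a space, lower-casing, whitespace splitting,
contraction-suffix stripping, stopword and digit-run removal. The
contraction table is `n't, 't, 's, 're, 've, 'll, 'd, 'm`; the root is kept
and the suffix discarded, which also strips possessive `'s` (the suffixes
are either stopwords or possessive markers, so nothing of value is lost).
Consequence: `don't → do`, `cell's → cell`. The packaged stoplist is the
standard 130-odd-word MEDLINE list; a second, curated list of low-content
research-prose words ships as `data/research_stopwords.txt` (a synthetic
reconstruction of the kind of institutional stoplist often used in
addition; apply it by passing it as the extra stoplist). By default the
extra list applies to topic-model vocabulary reduction, not to the base
tokenization.

MeSH cleaning drops `/qualifier` suffixes, removes check tags (Class 3) and
geographic descriptors (Class 4), strips leading `*` emphasis markers, and
de-duplicates per record. When records carry no class metadata, packaged
fallback lists of standard check tags and common geographic descriptors
decide removal.

Term–document matrices are sparse, terms × documents, with lexicographic
vocabulary order for reproducible files; MeSH matrices are binary. Terms in
fewer than `min_df` documents (default 4) are dropped and document
frequencies recomputed. Ahead of topic modeling the vocabulary is further
reduced: extra-stoplist words and terms with corpus count below 50 are
removed (all documents retained), and the retained-token fraction is
reported.

## Similarity measures

* **tf-idf cosine.** `tf` is within-document frequency (counts over the
  column sum), `idf_i = log(D/d_i)`. The log base (default 10) rescales all
  weights of a term uniformly and therefore cancels in the cosine; a test
  asserts this invariance.
* **LSA.** Truncated SVD of the tf-idf matrix (dense fallback when k
  approaches the smaller dimension). Document vectors follow
  `D = (S⁻¹ Tᵀ X)ᵀ` and similarities are dot products of rows of `D`. Note
  that with this normalization full-rank dot products equal
  `x_aᵀ T S⁻² Tᵀ x_b`, not the raw tf-idf dot products; the S-scaled
  vectors `D·S` recover the latter, and both are exposed. Defaults: k = 100
  (title/abstract), 200 (MeSH), capped by matrix shape.
* **BM25.** Okapi scoring with `k1 = 2.0`, `b = 0.75`, numerator
  `n_i(k1+1)` (the conventional kernel; configurable). IDF is the
  Robertson–Spärck Jones form `log10((N − d + 0.5)/(d + 0.5))`; this exact
  form is used because it reproduces both reference document-frequency
  cutoffs (21,324 at threshold 2.0 and 66,020 at 1.5 for N = 2,153,769).
  Terms whose IDF falls below the threshold are treated as absent. The
  threshold is *corpus-size dependent*: at a few hundred documents a cutoff
  of 2.0 leaves almost no terms, so small studies should lower it (the CLI
  exposes `--bm25-idf-threshold`). BM25 is asymmetric in (query, target);
  when both orientations of a pair survive filtering the larger value is
  kept.
* **Topic models.** A plain collapsed Gibbs sampler (single long chain,
  last-sample point estimate for the document–topic rows, which matches the
  single-chain-per-resolution design) with priors β = 0.01 and
  α = 0.05·N/(D·T), N = total tokens, recomputed per resolution. Documents
  emptied by vocabulary reduction get uniform rows. Full-scale resolutions
  are T ∈ {500, 1000, 2000} at 1200–1600 sweeps; the desk-scale defaults
  are {10, 20, 40} at 150 sweeps. The multi-resolution similarity is the
  equal-weight mean over resolutions of `1 − ½‖A_T − B_T‖₁`; the exact
  combination rule is a reconstruction consistent with equal weighting and
  the L1 norm, not an attested formula, and is labelled as such here.
* **PMRA proxy.** Rank lists are restricted to the corpus *without*
  re-ranking (surviving targets keep their original ranks) and converted by
  `sim = max(0, 1 − (rank − 1)/50)`; the floor keeps similarities
  nonnegative for ranks beyond 51.
* **SOM.** Online training with cosine best-matching-unit selection, a
  Gaussian neighborhood over grid distance, and linear decay of both the
  neighborhood radius (from half the grid side to 0.5) and the learning
  rate (0.5 → 0.02) — SOM_PAK-style defaults, since neither schedule is
  otherwise attested. Input dimensionality is reduced to the top-m most
  frequent terms (reference full-scale configuration: 275×275 neurons,
  m = 2,300). After assignment, under-populated neuron groups are merged
  greedily, smallest first, into the 4-neighborhood-adjacent group with the
  highest mean-weight-vector cosine (nearest occupied group by Manhattan
  grid distance when isolated) until every cluster holds ≥ 25 documents.
  The adjacency order and tie-breaks here are this package's choices. The
  SOM branch always yields full coverage.

## Top-n filtering

Each document's edge budget comes from `log` of the mean of its top-15
similarities, min–max rescaled across the corpus onto [5, 15] with half-up
rounding. The log is natural; under min–max rescaling any log base gives
the same budgets, so the choice is immaterial. Documents whose top-15 mean
is zero get the minimum budget; when every document has the same statistic
the range is degenerate and every document contributes the maximum (keeping
more information). Edge weights are never rescaled; unordered duplicates
keep the larger value.

## Consensus clustering

The base clusterer is deliberately pluggable (any seeded stochastic
partitioner of the edge graph). The default emulates the layout-based
original: a seeded weighted Fruchterman–Reingold layout in 2-D, cutting of
the longest 15% of edges by layout distance, average-link agglomeration of
positions cut at 2× the median surviving-edge length, and a final split of
clusters along surviving-edge connected components. No claim of
bit-compatibility with DrL/OpenOrd is made — the protocol's claims concern
the consensus stage, not layout internals.

Consensus: pairs co-clustered in at least 4 of 10 runs are processed in
descending count order (ties by id). A pair at or above the join threshold
(7/10) may found, extend, or merge clusters; a pair between the thresholds
may found a 2-document cluster or attach an unassigned document but never
merges two existing clusters. Documents in no pair at the membership
threshold stay unassigned — coverage is a reported quality signal, not a
guarantee. Undersized clusters (< 25) are merged into the cluster with the
highest mean retained-edge weight between members; an undersized cluster
with no edges to any other cluster is left in place and logged. Merging
never unassigns a document, so coverage is monotone under size enforcement.

## Validation

JSD uses log base 2, so it ranges over [0, 1] with `0·log 0 = 0`; the base
is configurable and recorded in reports. A cluster's word distribution
includes the focal document. Cluster JSD is the mean over member documents
of JSD(document, cluster); the baseline `JSD(rand)(n)` is the average over
random document subsets of size n (5,000 samples at full scale, fewer for
desk runs), sampled on a geometric size grid with linear interpolation
between sampled sizes. Per-cluster coherence defaults to the relative form
`(JSD(rand) − JSD_i)/JSD(rand)` with an "absolute" switch for the plain
difference; both are monotone transforms at fixed size, and the choice is a
labelled reconstruction, not an attested formula. The corpus value is the
cluster-size-weighted mean. Coherence is always computed from
title/abstract words, whichever source drove the clustering.

Concentration: grants with fewer than 4 articles are excluded (they cannot
distinguish solutions); unassigned articles do not count toward a grant's
n_i. The precision–recall curve orders clusters by descending linked-article
fraction (ties: larger cluster, then label); recall divides by *all* links
of retained grants, so low-coverage solutions pay a recall penalty. Pr80 is
linearly interpolated at recall 0.80 (undefined, with a warning, if the
curve never reaches it — whether to interpolate was an open choice).

## Synthetic data

The generator plants `n_clusters` word distributions over disjoint
vocabulary blocks plus a shared background block; block word probabilities
are Zipf-ranked (exponent 1.05) so document-frequency-based weighting and
IDF thresholds see realistic skew. Defaults — the package's standing study
conditions — are 500 documents, 10 clusters, 2,000-word vocabulary, 30%
background vocabulary, 0.8 cluster concentration, ~60 words per document,
40 grants averaging 6 articles at 0.9 home-cluster concentration. Grants
draw each article from their home cluster with the configured probability,
else from a uniformly random other cluster.

What it does *not* emulate: vocabulary growth, realistic MeSH ontology
structure, title/abstract register differences, citation structure, or the
heavy-tailed cluster-size distributions of real literature corpora. Tests
that pass on this generator therefore demonstrate that the machinery is
correct and that the protocol recovers strong planted structure; they do
not predict metric values on real MEDLINE-scale data.

## Problem sizes and numerical notes

Desk-scale defaults were chosen so the full test suite exercises every
stage on corpora of 120–500 documents: dense all-pairs similarity matrices
are used (quadratic memory is trivial at this size), the random-coherence
baseline uses 100–200 samples, and LDA runs 150–200 sweeps at T ≤ 40. The
Gibbs sampler, SOM training and layout are deterministic per seed; all
stage seeds derive from one master seed. Duplicate-pair handling, tie
breaks (always by id after the primary key) and the degenerate cases
(empty documents, zero vectors, degenerate min–max ranges, unlinked small
clusters) are fixed as described above and asserted in tests.

## Known limitations

* The consensus stage's two-tier procedure fixes a precedence (merges only
  through join-tier pairs) that the original prose left ambiguous; an
  alternative reading that lets membership-tier pairs chain clusters would
  give coarser solutions.
* The base clusterer's three internals (cut fraction, dendrogram cut
  factor, layout iterations) are heuristics tuned for blob-like planted
  graphs; pathological graphs (long chains, overlapping communities) may
  need a different base partitioner via the pluggable contract.
* `Pr80` and `max F1` are step-curve summaries; with very few clusters the
  interpolation at recall 0.80 is coarse.
* The PMRA branch consumes externally supplied rank lists; the underlying
  Poisson retrieval model is intentionally not reimplemented.
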