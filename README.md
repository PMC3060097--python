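# litsim

Benchmarking document-similarity approaches for clustering large
bibliographic corpora.

When a literature collection is partitioned into topical clusters, the
quality of the result depends heavily on *how* document–document similarity
was measured in the first place. `litsim` re-implements, at desk scale, a
benchmarking pipeline that compares similarity techniques for MEDLINE-style
records (title, abstract, MeSH descriptors, grant acknowledgements) by
running each one through an identical downstream protocol — top-n edge
filtering, multi-run consensus clustering — and scoring the resulting
cluster solutions with measures that are independent of the clustering
inputs. It is aimed at researchers in bibliometrics and science mapping who
want to evaluate similarity measures on their own corpora, or to study the
protocol itself on controlled synthetic data.

## Similarity techniques

Five techniques over two data sources (title/abstract words `ta`, MeSH
descriptors `mesh`), giving nine realized combinations:

| technique | definition |
|---|---|
| tf-idf cosine | `tf_ij = n_ij / Σ_k n_kj`, `idf_i = log(D/d_i)`; `cos_AB = A·B / (‖A‖‖B‖)` |
| LSA | truncated SVD of the tf-idf matrix `X ≈ T S Dᵀ`; doc vectors `D = (S⁻¹ Tᵀ X)ᵀ`, similarity = row dot products |
| BM25 (Okapi) | `Σ_i idf_i · n_i(k1+1) / (n_i + k1(1 − b + b·|D|/avgdl))` with `k1 = 2.0`, `b = 0.75`, `idf_i = log10((N − d_i + 0.5)/(d_i + 0.5))`, terms below an IDF cutoff (2.0 `ta` / 1.5 `mesh`) discarded |
| topic models | collapsed-Gibbs LDA at several resolutions T (priors β = 0.01, α = 0.05·N/(D·T)); similarity = mean over T of `1 − ½‖A_T − B_T‖₁` |
| PMRA proxy | related-article rank lists converted by `sim(rank) = 1 − (rank − 1)/50` |

plus a cosine self-organizing map (`som`/`mesh`) that assigns documents to
best-matching neurons and merges adjacent sparse neurons into clusters.

Downstream, every document contributes between 5 and 15 of its strongest
edges (scaled by `log(avg(top-15 sim))`), the base clusterer (seeded
force-directed layout + edge cutting + average link) is run 10 times, pairs
co-clustered in ≥ 4/10 runs form the consensus solution (two clusters merge
only through ≥ 7/10 pairs), and clusters under 25 documents are merged into
their most similar neighbor. Solutions are scored by:

* **coverage** — fraction of the corpus assigned;
* **textual coherence** — per-cluster mean Jensen–Shannon divergence (log
  base 2) between member documents and the cluster word distribution,
  normalized by the expected JSD of size-matched random clusters, weighted
  by cluster size;
* **concentration** — per-grant Herfindahl index `H_i = Σ_j (n_ij/n_i)²`
  weighted over grants, and a cluster-ordered precision–recall curve with
  `max F1 = max 2PR/(P+R)` and `Pr80` (precision at recall 0.80).

## Worked example

Generate a synthetic corpus of 200 documents with 5 planted topic clusters
and concentrated grant links, then benchmark BM25 on title/abstract words
(the IDF cutoff is corpus-size dependent, so it is lowered for a 200-doc
corpus):

```sh
litsim synth --n-docs 200 --n-clusters 5 --seed 7 --out-dir demo
litsim run-all --records demo/records.jsonl --method bm25 --source ta \
    --grants demo/grants.tsv --min-df 1 --bm25-idf-threshold 0.5 \
    --min-cluster-size 25 --seed 7 --out-dir demo_run
```

prints

```json
{
  "method": "bm25",
  "source": "ta",
  "seed": 7,
  "version": "0.1.0",
  "n_docs": 200,
  "coverage": 1.0,
  "n_clusters": 5,
  "max_cluster_size": 48,
  "coherence": 0.41121776991881454,
  "herfindahl": 0.8882508223740453,
  "max_f1": 0.7783775897286255,
  "pr80": 0.7200344177802253
}
```

Every document was clustered (coverage 1.0) into 5 clusters matching the
planted structure; the weighted coherence of 0.41 means member documents
are, on average, 41% less divergent from their clusters than random
same-size document sets would be; a weighted Herfindahl of 0.89 means each
grant's articles are almost entirely concentrated in a single cluster. The
run directory holds the edge file, partition, per-cluster coherence and
per-grant concentration reports, and the config needed to reproduce the run
bit for bit.

The library surface mirrors the pipeline: see `litsim.corpus`
(preprocessing), `litsim.similarity`, `litsim.graphfilter`,
`litsim.cluster`, `litsim.som`, `litsim.validate`, `litsim.synth`, and
`litsim.pipeline.run_pipeline`.

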