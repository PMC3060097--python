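"""Document-document similarity techniques.

Five techniques over two data sources (title/abstract words or MeSH
descriptors) produce the similarity values that feed the top-n filter:

* tf-idf cosine  -- tf_ij = n_ij / sum_k n_kj, idf_i = log(D/d_i), cosine of
  weighted term vectors.
* LSA            -- truncated SVD of the tf-idf matrix; document vectors
  D = (S^-1 T^T X)^T, similarity = dot products of rows of D.
* BM25 (Okapi)   -- probabilistic term weighting with saturation k1 and length
  normalization b, restricted to terms above an IDF threshold.
* Topic modeling -- collapsed-Gibbs LDA at several topic resolutions;
  similarity = mean over resolutions of 1 - L1/2 between doc-topic rows.
* PMRA proxy     -- rank-ordered related-article lists converted to
  similarities by sim(rank) = 1 - (rank-1)/50.

All-pairs helpers return dense doc x doc arrays and are meant for corpora of
up to a few thousand documents; the per-pair scalar functions define the
semantics and serve as oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .corpus import TermDocumentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TfidfMatrix",
    "Bm25Params",
    "Bm25Corpus",
    "LsaModel",
    "TopicModelSet",
    "RankList",
    "SimilarityEdgeList",
    "tfidf_transform",
    "cosine_similarity",
    "pairwise_cosine",
    "bm25_idf",
    "bm25_build_corpus",
    "bm25_similarity",
    "bm25_all_pairs",
    "lsa_fit",
    "lsa_all_pairs",
    "lda_fit",
    "fit_topic_models",
    "topic_similarity",
    "topic_all_pairs",
    "pmra_proxy_similarity",
    "restrict_rank_lists",
    "rank_lists_to_similarities",
]


# ---------------------------------------------------------------------------
# tf-idf cosine
# ---------------------------------------------------------------------------

@dataclass
class TfidfMatrix:
    """tf x idf weights (terms x docs), tf column-normalized, idf = log(D/d_i)."""

    terms: list[str]
    doc_ids: list[str]
    weights: sp.csr_matrix
    idf: np.ndarray
    log_base: float = 10.0


def tfidf_transform(tdm: TermDocumentMatrix, log_base: float = 10.0) -> TfidfMatrix:
    """Weight a count matrix by tf x idf.

    tf_ij = n_ij / sum_k n_kj (within-document frequency); idf_i = log(D/d_i)
    in the given base.  The base is immaterial for downstream cosines (a
    global rescaling of rows cancels); it matters only for matrix dumps.
    Zero-length documents keep all-zero columns.
    """
    if tdm.n_docs == 0 or tdm.n_terms == 0:
        raise ValueError("empty term-document matrix")
    counts = tdm.counts.astype(np.float64)
    col_sums = np.asarray(counts.sum(axis=0)).ravel()
    empty = col_sums == 0
    if empty.any():
        logger.warning("%d zero-length documents in tf-idf transform", int(empty.sum()))
    inv = np.divide(1.0, col_sums, out=np.zeros_like(col_sums), where=~empty)
    tf = counts @ sp.diags(inv)
    d = tdm.vocabulary.doc_freq.astype(np.float64)
    idf = np.log(tdm.n_docs / d) / math.log(log_base)
    weights = sp.csr_matrix(sp.diags(idf) @ tf)
    return TfidfMatrix(list(tdm.vocabulary.terms), list(tdm.doc_ids), weights, idf, log_base)


def cosine_similarity(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """cos(A,B) = A.B / (||A|| ||B||); zero vectors yield 0 with a warning."""
    a = np.asarray(vec_a, dtype=np.float64).ravel()
    b = np.asarray(vec_b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("cosine similarity of a zero vector reported as 0")
        return 0.0
    return float(a @ b / (na * nb))


def pairwise_cosine(tfidf: TfidfMatrix) -> np.ndarray:
    """Dense doc x doc cosine matrix of tf-idf columns (zero docs -> 0 rows)."""
    W = tfidf.weights.tocsc()
    norms = np.sqrt(np.asarray(W.multiply(W).sum(axis=0)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    Wn = W @ sp.diags(inv)
    return np.asarray((Wn.T @ Wn).todense())


# ---------------------------------------------------------------------------
# BM25
# ---------------------------------------------------------------------------

@dataclass
class Bm25Params:
    k1: float = 2.0
    b: float = 0.75
    idf_threshold: float = 2.0  # 2.0 for title/abstract, 1.5 for MeSH
    log_base: float = 10.0
    k1_plus_1_numerator: bool = True  # classic Okapi numerator n_i (k1+1)

    def __post_init__(self) -> None:
        if self.k1 <= 0 or not (0 <= self.b <= 1):
            raise ValueError("require k1 > 0 and 0 <= b <= 1")


@dataclass
class Bm25Corpus:
    """Per-document lengths, the corpus mean length, and per-term IDF."""

    doc_len: np.ndarray
    avgdl: float
    N: int
    idf: np.ndarray


def bm25_idf(N: int, d: int, log_base: float = 10.0) -> float:
    """Robertson-Sparck-Jones IDF: log((N - d + 0.5) / (d + 0.5)).

    Monotone decreasing in the document frequency d; negative once a term
    appears in more than half of the corpus.
    """
    if not (0 < d <= N):
        raise ValueError("require 0 < d <= N")
    return math.log((N - d + 0.5) / (d + 0.5)) / math.log(log_base)


def smallest_excluded_df(N: int, idf_threshold: float, log_base: float = 10.0) -> int:
    """Smallest integer document frequency whose IDF falls below the threshold."""
    lo, hi = 1, N
    while lo < hi:  # idf is monotone decreasing in d
        mid = (lo + hi) // 2
        if bm25_idf(N, mid, log_base) < idf_threshold:
            hi = mid
        else:
            lo = mid + 1
    return lo


def bm25_build_corpus(tdm: TermDocumentMatrix, params: Bm25Params) -> Bm25Corpus:
    doc_len = np.asarray(tdm.counts.sum(axis=0)).ravel().astype(np.float64)
    avgdl = float(doc_len.mean())
    N = tdm.n_docs
    d = tdm.vocabulary.doc_freq
    idf = np.array([bm25_idf(N, int(di), params.log_base) for di in d])
    return Bm25Corpus(doc_len, avgdl, N, idf)


def bm25_similarity(
    query_doc: str,
    target_doc: str,
    tdm: TermDocumentMatrix,
    params: Bm25Params | None = None,
    corpus: Bm25Corpus | None = None,
) -> float:
    """Okapi BM25 score of ``target_doc`` against the terms of ``query_doc``.

    score = sum over query terms i of
        idf_i * n_i (k1+1) / (n_i + k1 (1 - b + b |D|/avgdl))
    with n_i the count of term i in the target and |D| the target length.
    Terms with idf below ``params.idf_threshold`` are treated as absent.
    Asymmetric in (query, target).
    """
    params = params or Bm25Params()
    corpus = corpus or bm25_build_corpus(tdm, params)
    dindex = tdm.doc_index()
    q, t = dindex[query_doc], dindex[target_doc]
    col_q = tdm.counts.getcol(q)
    col_t = np.asarray(tdm.counts.getcol(t).todense()).ravel()
    numer_k = (params.k1 + 1.0) if params.k1_plus_1_numerator else 1.0
    K = params.k1 * (1.0 - params.b + params.b * corpus.doc_len[t] / corpus.avgdl)
    score = 0.0
    for i in col_q.nonzero()[0]:
        if corpus.idf[i] < params.idf_threshold:
            continue
        n_i = col_t[i]
        if n_i > 0:
            score += corpus.idf[i] * n_i * numer_k / (n_i + K)
    return float(score)


def bm25_all_pairs(
    tdm: TermDocumentMatrix,
    params: Bm25Params | None = None,
) -> np.ndarray:
    """Dense query x target BM25 score matrix (diagonal zeroed)."""
    params = params or Bm25Params()
    corpus = bm25_build_corpus(tdm, params)
    keep = corpus.idf >= params.idf_threshold
    idf = np.where(keep, corpus.idf, 0.0)
    counts = tdm.counts.astype(np.float64).tocsc()
    numer_k = (params.k1 + 1.0) if params.k1_plus_1_numerator else 1.0
    K = params.k1 * (1.0 - params.b + params.b * corpus.doc_len / corpus.avgdl)
    # W[i, t] = idf_i * n_it (k1+1) / (n_it + K_t): target-side term weights
    coo = counts.tocoo()
    w = idf[coo.row] * coo.data * numer_k / (coo.data + K[coo.col])
    W = sp.csr_matrix((w, (coo.row, coo.col)), shape=counts.shape)
    presence = sp.csr_matrix(
        (keep[coo.row].astype(np.float64), (coo.row, coo.col)), shape=counts.shape
    )
    scores = np.asarray((presence.T @ W).todense())
    np.fill_diagonal(scores, 0.0)
    return scores


# ---------------------------------------------------------------------------
# LSA
# ---------------------------------------------------------------------------

@dataclass
class LsaModel:
    """Truncated factorization X ~= T S D^T of the tf-idf matrix.

    ``doc_vectors`` holds D = (S^-1 T^T X)^T, the similarity basis; scaled
    vectors D S (= (T^T X)^T) reproduce tf-idf dot products at full rank.
    """

    k: int
    singular_values: np.ndarray  # descending, strictly positive
    term_vectors: np.ndarray     # terms x k
    doc_vectors: np.ndarray      # docs x k

    @property
    def scaled_doc_vectors(self) -> np.ndarray:
        return self.doc_vectors * self.singular_values


def lsa_fit(tfidf: TfidfMatrix, k: int = 100) -> LsaModel:
    """Top-k singular triples of the tf-idf matrix (default k=100 for
    title/abstract, 200 for MeSH at full scale)."""
    X = sp.csr_matrix(tfidf.weights, dtype=np.float64)
    n_terms, n_docs = X.shape
    kmax = min(n_terms, n_docs)
    if not (1 <= k <= kmax):
        raise ValueError(f"k must be in [1, {kmax}]")
    if k >= kmax - 1:  # svds needs k < min(shape); fall back to dense
        U, s, _ = np.linalg.svd(np.asarray(X.todense()), full_matrices=False)
        U, s = U[:, :k], s[:k]
    else:
        U, s, _ = scipy.sparse.linalg.svds(X, k=k)
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
    pos = s > 1e-12 * (s[0] if s.size else 1.0)
    U, s = U[:, pos], s[pos]
    doc_vectors = (np.diag(1.0 / s) @ U.T @ X).T
    return LsaModel(k=len(s), singular_values=s, term_vectors=U,
                    doc_vectors=np.asarray(doc_vectors))


def lsa_all_pairs(model: LsaModel) -> np.ndarray:
    """Doc x doc similarity as dot products of reduced document vectors."""
    return model.doc_vectors @ model.doc_vectors.T


# ---------------------------------------------------------------------------
# Topic modeling (collapsed-Gibbs LDA)
# ---------------------------------------------------------------------------

def lda_alpha(total_tokens: int, n_docs: int, n_topics: int) -> float:
    """Symmetric document-topic prior alpha = 0.05 N / (D T)."""
    return 0.05 * total_tokens / (n_docs * n_topics)


def lda_fit(
    tdm_reduced: TermDocumentMatrix,
    T: int,
    iterations: int = 200,
    seed: int = 0,
    beta: float = 0.01,
    alpha: float | None = None,
) -> np.ndarray:
    """Collapsed Gibbs sampler for LDA; returns docs x T topic probabilities.

    Priors: beta = 0.01 on topic-word, alpha = 0.05 N / (D T) on doc-topic
    unless overridden.  The doc-topic point estimate is taken from the final
    sample (single long chain).  Empty documents get a uniform row.
    Deterministic for a fixed seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    D = tdm_reduced.n_docs
    W = tdm_reduced.n_terms
    counts = tdm_reduced.counts.tocoo()
    # expand to token streams
    doc_of = np.repeat(counts.col, counts.data.astype(np.int64))
    word_of = np.repeat(counts.row, counts.data.astype(np.int64))
    n_tokens = doc_of.size
    if alpha is None:
        alpha = lda_alpha(max(n_tokens, 1), max(D, 1), T)
    rng = np.random.default_rng(seed)
    if T == 1 or n_tokens == 0:
        theta = np.full((D, T), 1.0 / T)
        return theta
    z = rng.integers(0, T, size=n_tokens)
    ndt = np.zeros((D, T), dtype=np.int64)
    nwt = np.zeros((W, T), dtype=np.int64)
    nt = np.zeros(T, dtype=np.int64)
    np.add.at(ndt, (doc_of, z), 1)
    np.add.at(nwt, (word_of, z), 1)
    np.add.at(nt, z, 1)
    wbeta = W * beta
    for _ in range(iterations):
        u = rng.random(n_tokens)
        for n in range(n_tokens):
            d, w, t = doc_of[n], word_of[n], z[n]
            ndt[d, t] -= 1
            nwt[w, t] -= 1
            nt[t] -= 1
            p = (ndt[d] + alpha) * (nwt[w] + beta) / (nt + wbeta)
            cp = np.cumsum(p)
            t = int(np.searchsorted(cp, u[n] * cp[-1], side="right"))
            t = min(t, T - 1)
            z[n] = t
            ndt[d, t] += 1
            nwt[w, t] += 1
            nt[t] += 1
    doc_len = np.asarray(tdm_reduced.counts.sum(axis=0)).ravel()
    theta = (ndt + alpha) / (doc_len[:, None] + T * alpha)
    theta /= theta.sum(axis=1, keepdims=True)
    theta[doc_len == 0] = 1.0 / T
    return theta


@dataclass
class TopicModelSet:
    """Doc-topic rows at several resolutions (full scale: T = 500/1000/2000)."""

    resolutions: list[int]
    doc_topic: dict[int, np.ndarray]  # T -> docs x T probability rows
    doc_ids: list[str]
    beta: float = 0.01
    iterations: dict[int, int] = field(default_factory=dict)


def fit_topic_models(
    tdm_reduced: TermDocumentMatrix,
    resolutions: Sequence[int] = (10, 20, 40),
    iterations: int = 200,
    seed: int = 0,
) -> TopicModelSet:
    """Fit one LDA chain per resolution (desk-scale default T in {10,20,40})."""
    doc_topic = {}
    iters = {}
    for i, T in enumerate(resolutions):
        doc_topic[T] = lda_fit(tdm_reduced, T, iterations=iterations, seed=seed + i)
        iters[T] = iterations
    return TopicModelSet(list(resolutions), doc_topic, list(tdm_reduced.doc_ids),
                         iterations=iters)


def topic_similarity(
    doc_a_rows: Mapping[int, np.ndarray],
    doc_b_rows: Mapping[int, np.ndarray],
) -> float:
    """Equal-weight mean over resolutions of 1 - ||A_T - B_T||_1 / 2.

    Symmetric, in [0, 1], and 1 exactly when the rows agree at every
    resolution.
    """
    if set(doc_a_rows) != set(doc_b_rows):
        raise ValueError("mismatched topic resolutions")
    vals = []
    for T in sorted(doc_a_rows):
        a, b = np.asarray(doc_a_rows[T]), np.asarray(doc_b_rows[T])
        vals.append(1.0 - 0.5 * float(np.abs(a - b).sum()))
    return float(np.mean(vals))


def topic_all_pairs(models: TopicModelSet) -> np.ndarray:
    """Dense doc x doc multi-resolution topic similarity (diagonal zeroed)."""
    n = len(models.doc_ids)
    sims = np.zeros((n, n))
    for T in models.resolutions:
        theta = models.doc_topic[T]
        l1 = np.abs(theta[:, None, :] - theta[None, :, :]).sum(axis=2)
        sims += 1.0 - 0.5 * l1
    sims /= len(models.resolutions)
    np.fill_diagonal(sims, 0.0)
    return sims


# ---------------------------------------------------------------------------
# PMRA rank proxy
# ---------------------------------------------------------------------------

@dataclass
class RankList:
    """Rank-ordered related documents for one source document."""

    source: str
    targets: list[tuple[str, int]]  # (target doc_id, rank >= 1)


def pmra_proxy_similarity(rank: int) -> float:
    """Proxy similarity for a related-article rank: max(0, 1 - (rank-1)/50).

    Rank 1 -> 1.00, rank 2 -> 0.98, ..., floor of 0 from rank 51 on.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    return max(0.0, 1.0 - (rank - 1) / 50.0)


def restrict_rank_lists(
    lists: Iterable[RankList], corpus_ids: set[str]
) -> list[RankList]:
    """Drop targets outside the corpus; surviving targets keep their original
    rank values (no re-ranking)."""
    out = []
    for rl in lists:
        kept = [(t, r) for t, r in rl.targets if t in corpus_ids]
        out.append(RankList(rl.source, kept))
    return out


def rank_lists_to_similarities(
    lists: Iterable[RankList],
) -> dict[str, list[tuple[str, float]]]:
    """Per-document (neighbor, proxy similarity) lists for the top-n filter."""
    return {
        rl.source: [(t, pmra_proxy_similarity(r)) for t, r in rl.targets]
        for rl in lists
    }


def read_rank_lists(path: str | Path) -> list[RankList]:
    """TSV (source_id, target_id, rank), grouped by source in file order."""
    by_source: dict[str, list[tuple[str, int]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            src, tgt, rank = line.split("\t")
            if src not in by_source:
                by_source[src] = []
                order.append(src)
            by_source[src].append((tgt, int(rank)))
    return [RankList(s, by_source[s]) for s in order]


def write_rank_lists(lists: Iterable[RankList], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rl in lists:
            for tgt, rank in rl.targets:
                fh.write(f"{rl.source}\t{tgt}\t{rank}\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

@dataclass
class SimilarityEdgeList:
    """De-duplicated weighted document pairs with doc_a < doc_b."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for a, b, s in self.edges:
            if a >= b:
                raise ValueError(f"pair not ordered: {a!r} >= {b!r}")
            if not (math.isfinite(s) and s >= 0):
                raise ValueError(f"bad similarity {s} for pair ({a},{b})")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a},{b})")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.edges)

    def doc_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {(a, b): s for a, b, s in self.edges}


def write_edges(edges: SimilarityEdgeList, path: str | Path) -> None:
    """TSV triples (id_a, id_b, similarity to 6 decimals), pairs sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, s in sorted(edges.edges):
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def read_edges(path: str | Path) -> SimilarityEdgeList:
    triples = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b, s = line.split("\t")
            triples.append((a, b, float(s)))
    return SimilarityEdgeList(triples)
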