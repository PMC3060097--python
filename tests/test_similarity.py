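"""Oracle checks for the five similarity techniques."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from litsim.corpus import build_term_document_matrix
from litsim.similarity import (
    Bm25Params,
    RankList,
    SimilarityEdgeList,
    bm25_all_pairs,
    bm25_build_corpus,
    bm25_idf,
    bm25_similarity,
    cosine_similarity,
    lda_alpha,
    lda_fit,
    lsa_all_pairs,
    lsa_fit,
    pairwise_cosine,
    pmra_proxy_similarity,
    read_edges,
    restrict_rank_lists,
    smallest_excluded_df,
    tfidf_transform,
    topic_similarity,
    write_edges,
)

FULL_SCALE_N = 2_153_769


class TestTfidf:
    def test_ubiquitous_term_has_zero_weight(self, toy_tdm):
        docs = {"a": ["x", "y"], "b": ["x"], "c": ["x", "z", "z"]}
        tdm = build_term_document_matrix(docs, min_df=1)
        tfidf = tfidf_transform(tdm)
        i = tfidf.terms.index("x")
        assert tfidf.idf[i] == 0.0
        assert tfidf.weights[i].toarray().max() == 0.0

    def test_two_by_two_hand_computation(self):
        # d1 = [a, a, b], d2 = [b]; D=2, d_a=1, d_b=2
        tdm = build_term_document_matrix({"d1": ["a", "a", "b"], "d2": ["b"]}, min_df=1)
        tfidf = tfidf_transform(tdm)
        w = tfidf.weights.toarray()
        idf_a = math.log10(2 / 1)
        assert w[0, 0] == pytest.approx((2 / 3) * idf_a)
        assert w[1, 0] == 0.0  # b in every doc -> idf 0
        assert w[1, 1] == 0.0

    def test_cosine_invariant_to_idf_log_base(self, small_synth):
        _, records, _, _ = small_synth
        from litsim.corpus import tokenize_title_abstract, default_stopwords

        stop = default_stopwords()
        docs = {
            r.doc_id: tokenize_title_abstract(r.title, r.abstract, stop)
            for r in records[:40]
        }
        tdm = build_term_document_matrix(docs, min_df=1)
        c10 = pairwise_cosine(tfidf_transform(tdm, log_base=10))
        ce = pairwise_cosine(tfidf_transform(tdm, log_base=math.e))
        np.testing.assert_allclose(c10, ce, atol=1e-12)


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_hand_value(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / math.sqrt(2), abs=1e-5)

    def test_zero_vector_reported_as_zero(self):
        assert cosine_similarity([0, 0], [1, 1]) == 0.0

    def test_pairwise_matches_brute_force(self, rng):
        docs = {
            f"d{j}": list(rng.choice([f"w{i}" for i in range(15)], size=rng.integers(2, 10)))
            for j in range(20)
        }
        tdm = build_term_document_matrix(docs, min_df=1)
        tfidf = tfidf_transform(tdm)
        sims = pairwise_cosine(tfidf)
        W = tfidf.weights.toarray()
        for a in range(20):
            for b in range(20):
                assert sims[a, b] == pytest.approx(
                    cosine_similarity(W[:, a], W[:, b]), abs=1e-9
                )


class TestBm25:
    def test_printed_cutoffs(self):
        assert smallest_excluded_df(FULL_SCALE_N, 2.0) == 21_324
        assert smallest_excluded_df(FULL_SCALE_N, 1.5) == 66_020

    def test_idf_zero_at_half_corpus(self):
        assert bm25_idf(10, 5) == pytest.approx(0.0)

    def test_idf_monotone_decreasing(self):
        vals = [bm25_idf(1000, d) for d in range(1, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_idf_rejects_bad_df(self):
        with pytest.raises(ValueError):
            bm25_idf(10, 11)

    def test_default_constants(self):
        params = Bm25Params()
        assert (params.k1, params.b) == (2.0, 0.75)

    def test_no_shared_terms_above_threshold(self):
        tdm = build_term_document_matrix({"q": ["a"], "d": ["b"], "e": ["a", "b"]}, min_df=1)
        assert bm25_similarity("q", "d", tdm, Bm25Params(idf_threshold=-10)) == 0.0

    def test_three_doc_hand_oracle(self):
        """Score equals an independently evaluated term-by-term sum."""
        docs = {"q": ["a", "b", "b"], "d": ["a", "a", "b", "c"], "e": ["c"]}
        tdm = build_term_document_matrix(docs, min_df=1)
        params = Bm25Params(idf_threshold=-10.0)
        corpus = bm25_build_corpus(tdm, params)
        got = bm25_similarity("q", "d", tdm, params, corpus)
        # brute force from the definition
        avgdl = (3 + 4 + 1) / 3
        dlen = 4
        K = 2.0 * (1 - 0.75 + 0.75 * dlen / avgdl)
        expected = 0.0
        for term, n_t in (("a", 2), ("b", 1)):  # counts in target d
            d_i = {"a": 2, "b": 2, "c": 2}[term]
            idf = math.log10((3 - d_i + 0.5) / (d_i + 0.5))
            expected += idf * n_t * 3.0 / (n_t + K)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_all_pairs_matches_scalar_and_is_asymmetric(self, rng):
        docs = {
            f"d{j}": list(rng.choice([f"w{i}" for i in range(10)], size=rng.integers(2, 8)))
            for j in range(12)
        }
        tdm = build_term_document_matrix(docs, min_df=1)
        params = Bm25Params(idf_threshold=0.0)
        corpus = bm25_build_corpus(tdm, params)
        scores = bm25_all_pairs(tdm, params)
        ids = tdm.doc_ids
        for a in range(12):
            for b in range(12):
                if a == b:
                    continue
                assert scores[a, b] == pytest.approx(
                    bm25_similarity(ids[a], ids[b], tdm, params, corpus), abs=1e-9
                )
        assert not np.allclose(scores, scores.T)
        assert (scores >= 0).all()


class TestLsa:
    def test_rank_one_exact(self):
        import scipy.sparse as sp
        from litsim.similarity import TfidfMatrix

        X = np.outer([1.0, 2.0], [3.0, 1.0, 2.0])  # rank-1, 2 terms x 3 docs
        tfidf = TfidfMatrix(["t0", "t1"], ["a", "b", "c"], sp.csr_matrix(X), np.ones(2))
        model = lsa_fit(tfidf, k=1)
        recon = (model.term_vectors * model.singular_values) @ model.doc_vectors.T
        np.testing.assert_allclose(recon, X, atol=1e-12)
        sims = lsa_all_pairs(model)
        loadings = model.doc_vectors[:, 0]
        np.testing.assert_allclose(sims, np.outer(loadings, loadings), atol=1e-12)

    def test_singular_values_match_dense_oracle(self, rng):
        X = rng.random((30, 20))
        import scipy.sparse as sp
        from litsim.similarity import TfidfMatrix

        tfidf = TfidfMatrix(
            [f"t{i}" for i in range(30)], [f"d{j}" for j in range(20)],
            sp.csr_matrix(X), np.ones(30),
        )
        model = lsa_fit(tfidf, k=5)
        dense = np.linalg.svd(X, compute_uv=False)[:5]
        np.testing.assert_allclose(model.singular_values, dense, atol=1e-6)

    def test_full_rank_scaled_vectors_reproduce_dot_products(self, rng):
        """Completeness limit: at k = min(terms, docs), dot products of the
        S-scaled document vectors equal tf-idf column dot products."""
        X = rng.random((8, 6))
        import scipy.sparse as sp
        from litsim.similarity import TfidfMatrix

        tfidf = TfidfMatrix(
            [f"t{i}" for i in range(8)], [f"d{j}" for j in range(6)],
            sp.csr_matrix(X), np.ones(8),
        )
        model = lsa_fit(tfidf, k=6)
        scaled = model.scaled_doc_vectors
        np.testing.assert_allclose(scaled @ scaled.T, X.T @ X, atol=1e-6)

    def test_doc_vectors_formula(self, rng):
        X = rng.random((10, 7))
        import scipy.sparse as sp
        from litsim.similarity import TfidfMatrix

        tfidf = TfidfMatrix(
            [f"t{i}" for i in range(10)], [f"d{j}" for j in range(7)],
            sp.csr_matrix(X), np.ones(10),
        )
        model = lsa_fit(tfidf, k=3)
        expected = (np.diag(1 / model.singular_values) @ model.term_vectors.T @ X).T
        np.testing.assert_allclose(model.doc_vectors, expected, atol=1e-10)
        sims = lsa_all_pairs(model)
        np.testing.assert_allclose(sims, model.doc_vectors @ model.doc_vectors.T)


class TestLda:
    def test_single_topic_rows(self, toy_tdm):
        _, tdm = toy_tdm
        theta = lda_fit(tdm, T=1, iterations=5, seed=0)
        np.testing.assert_array_equal(theta, np.ones((tdm.n_docs, 1)))

    def test_alpha_formula(self):
        assert lda_alpha(243_724_698, 2_153_769, 500) == pytest.approx(
            0.05 * 243_724_698 / (2_153_769 * 500)
        )

    def test_rows_sum_to_one_and_deterministic(self, toy_tdm):
        _, tdm = toy_tdm
        t1 = lda_fit(tdm, T=3, iterations=20, seed=5)
        t2 = lda_fit(tdm, T=3, iterations=20, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_allclose(t1.sum(axis=1), 1.0, atol=1e-9)

    def test_iterations_validation(self, toy_tdm):
        _, tdm = toy_tdm
        with pytest.raises(ValueError):
            lda_fit(tdm, T=2, iterations=0, seed=0)


class TestTopicSimilarity:
    def test_identical_rows(self):
        rows = {10: np.array([0.2, 0.8]), 20: np.array([0.5, 0.5])}
        assert topic_similarity(rows, rows) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = {5: np.array([1.0, 0.0])}
        b = {5: np.array([0.0, 1.0])}
        assert topic_similarity(a, b) == pytest.approx(0.0)

    def test_half_overlap(self):
        a = {5: np.array([0.5, 0.5])}
        b = {5: np.array([1.0, 0.0])}
        assert topic_similarity(a, b) == pytest.approx(0.5)

    def test_mismatched_resolutions_rejected(self):
        with pytest.raises(ValueError):
            topic_similarity({5: np.array([1.0])}, {6: np.array([1.0])})

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = {T: rng.dirichlet(np.ones(T)) for T in (3, 5)}
        b = {T: rng.dirichlet(np.ones(T)) for T in (3, 5)}
        s_ab = topic_similarity(a, b)
        assert s_ab == pytest.approx(topic_similarity(b, a), abs=1e-12)
        assert -1e-12 <= s_ab <= 1 + 1e-12


class TestPmra:
    @pytest.mark.parametrize("rank, sim", [(1, 1.0), (2, 0.98), (26, 0.5), (51, 0.0), (99, 0.0)])
    def test_rank_to_similarity(self, rank, sim):
        assert pmra_proxy_similarity(rank) == pytest.approx(sim)

    def test_rank_below_one_rejected(self):
        with pytest.raises(ValueError):
            pmra_proxy_similarity(0)

    def test_restrict_keeps_original_ranks(self):
        lists = [RankList("s", [("x", 1), ("y", 2), ("z", 3)])]
        out = restrict_rank_lists(lists, {"s", "x", "z"})
        assert out[0].targets == [("x", 1), ("z", 3)]

    def test_restrict_identity_and_empty(self):
        lists = [RankList("s", [("x", 1)])]
        assert restrict_rank_lists(lists, {"s", "x"})[0].targets == [("x", 1)]
        assert restrict_rank_lists(lists, set())[0].targets == []


class TestEdgeList:
    def test_rejects_duplicates_and_order(self):
        with pytest.raises(ValueError):
            SimilarityEdgeList([("b", "a", 1.0)])
        with pytest.raises(ValueError):
            SimilarityEdgeList([("a", "b", 1.0), ("a", "b", 0.5)])

    def test_tsv_roundtrip(self, tmp_path):
        edges = SimilarityEdgeList([("a", "b", 0.123456789), ("a", "c", 1.0)])
        write_edges(edges, tmp_path / "e.tsv")
        back = read_edges(tmp_path / "e.tsv")
        assert back.edges == [("a", "b", 0.123457), ("a", "c", 1.0)]
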