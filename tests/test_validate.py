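"""JSD coherence, random baselines, Herfindahl and precision-recall."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import jensenshannon

from litsim.cluster import Partition
from litsim.corpus import build_term_document_matrix
from litsim.validate import (
    BaselineInterpolator,
    GrantLinkSet,
    cluster_coherence,
    coherence_report,
    herfindahl,
    jsd,
    precision_recall,
    random_baseline,
)


class TestJsd:
    def test_identical_distributions(self):
        p = np.array([0.3, 0.7])
        assert jsd(p, p) == 0.0

    def test_disjoint_supports_maximal(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-5)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.6], [1.0, 0.0])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_bounds_and_scipy_cross_check(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        v = jsd(p, q)
        assert v == pytest.approx(jsd(q, p), abs=1e-12)
        assert -1e-12 <= v <= 1 + 1e-12
        # independent route: scipy returns the square root of the divergence
        assert v == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-9)


class TestClusterCoherence:
    def test_identical_documents(self):
        counts = np.tile([3, 1, 0], (5, 1))
        jsd_i, coh = cluster_coherence(counts, baseline=0.4)
        assert jsd_i == pytest.approx(0.0)
        assert coh == pytest.approx(1.0)

    def test_jsd_equal_to_baseline_gives_zero(self):
        counts = np.array([[5, 0], [0, 5]])
        jsd_i, _ = cluster_coherence(counts, baseline=0.4)
        _, coh = cluster_coherence(counts, baseline=jsd_i)
        assert coh == pytest.approx(0.0)

    def test_absolute_normalization(self):
        counts = np.array([[5, 0], [0, 5]])
        jsd_i, coh = cluster_coherence(counts, baseline=0.9, normalization="absolute")
        assert coh == pytest.approx(0.9 - jsd_i)

    def test_five_doc_brute_force_average(self, rng):
        counts = rng.integers(0, 6, size=(5, 8)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        jsd_i, _ = cluster_coherence(counts, baseline=0.5)
        q = counts.sum(axis=0) / counts.sum()
        vals = [jsd(row / row.sum(), q) for row in counts]
        assert jsd_i == pytest.approx(float(np.mean(vals)), abs=1e-9)

    def test_focal_document_included_in_cluster_distribution(self):
        # one doc: q == p, so JSD 0 by the inclusive convention
        jsd_i, _ = cluster_coherence(np.array([[2.0, 1.0]]), baseline=0.5)
        assert jsd_i == pytest.approx(0.0)


class TestRandomBaseline:
    def test_size_one_is_zero(self, rng):
        X = rng.integers(1, 5, size=(10, 6)).astype(float)
        out = random_baseline(X, [1], n_samples=10, seed=0)
        assert out[1] == 0.0

    def test_monotone_in_size_on_heterogeneous_corpus(self):
        """Larger random clusters are more divergent: check the trend over
        3 seeds on a two-block corpus (500 samples)."""
        base = np.random.default_rng(99)
        X = np.zeros((40, 20))
        X[:20, :10] = base.integers(1, 6, size=(20, 10))
        X[20:, 10:] = base.integers(1, 6, size=(20, 10))
        for seed in range(3):
            out = random_baseline(X, [2, 5, 10, 20], n_samples=500, seed=seed)
            vals = [out[s] for s in (2, 5, 10, 20)]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_size_two_matches_exhaustive_enumeration(self):
        """Disjoint-vocabulary groups: the size-2 baseline must sit within 3
        standard errors of the exact mean over all pairs."""
        base = np.random.default_rng(7)
        X = np.zeros((16, 8))
        X[:8, :4] = base.integers(1, 5, size=(8, 4))
        X[8:, 4:] = base.integers(1, 5, size=(8, 4))
        vals = []
        for i, j in itertools.combinations(range(16), 2):
            q = X[i] + X[j]
            q = q / q.sum()
            pi = X[i] / X[i].sum()
            pj = X[j] / X[j].sum()
            vals.append((jsd(pi, q) + jsd(pj, q)) / 2)
        exact_mean = float(np.mean(vals))
        n_samples = 400
        out = random_baseline(X, [2], n_samples=n_samples, seed=1)
        se = float(np.std(vals, ddof=1)) / math.sqrt(n_samples)
        assert abs(out[2] - exact_mean) <= 3 * se

    def test_oversized_request_rejected(self, rng):
        X = rng.integers(1, 4, size=(5, 3)).astype(float)
        with pytest.raises(ValueError):
            random_baseline(X, [6], n_samples=5, seed=0)

    def test_interpolator(self):
        interp = BaselineInterpolator({2: 0.2, 10: 0.6})
        assert interp(2) == 0.2
        assert interp(6) == pytest.approx(0.4)
        assert interp(10) == 0.6


class TestHerfindahl:
    def test_all_in_one_cluster(self):
        links = GrantLinkSet({"g": ["a", "b", "c", "d"]})
        part = Partition({d: 0 for d in "abcd"}, set())
        per_grant, h = herfindahl(links, part)
        assert per_grant["g"] == pytest.approx(1.0)
        assert h == pytest.approx(1.0)

    def test_four_clusters_quarter(self):
        links = GrantLinkSet({"g": ["a", "b", "c", "d"]})
        part = Partition({"a": 0, "b": 1, "c": 2, "d": 3}, set())
        per_grant, _ = herfindahl(links, part)
        assert per_grant["g"] == pytest.approx(0.25)

    def test_three_grant_weighted_hand_computation(self):
        links = GrantLinkSet(
            {
                "g1": ["a", "b", "c", "d"],          # 3/1 split -> 10/16
                "g2": ["e", "f", "g", "h", "i"],     # 5 together -> 1
                "g3": ["a", "e", "j", "k"],          # 2/1/1 -> 6/16
            }
        )
        assignments = {d: 0 for d in "abcj"}
        assignments.update({d: 1 for d in "defghik"})
        part = Partition(assignments, set())
        per_grant, h = herfindahl(links, part)
        assert per_grant["g1"] == pytest.approx((3 / 4) ** 2 + (1 / 4) ** 2, abs=1e-12)
        assert per_grant["g2"] == pytest.approx(1.0, abs=1e-12)
        expected_g3 = (2 / 4) ** 2 + (2 / 4) ** 2
        assert per_grant["g3"] == pytest.approx(expected_g3, abs=1e-12)
        expected_h = (4 * per_grant["g1"] + 5 * 1.0 + 4 * expected_g3) / 13
        assert h == pytest.approx(expected_h, abs=1e-12)

    def test_min_articles_filter_and_unassigned_exclusion(self):
        links = GrantLinkSet({"small": ["a", "b"], "g": ["a", "b", "c", "d"]})
        part = Partition({"a": 0, "b": 0, "c": 1}, {"d"})
        per_grant, _ = herfindahl(links, part)
        assert "small" not in per_grant  # below the 4-article floor
        assert per_grant["g"] == pytest.approx((2 / 3) ** 2 + (1 / 3) ** 2)

    def test_bounds_and_refinement_property(self, rng):
        """1/C <= H_i <= 1, and splitting clusters never increases H."""
        docs = [f"d{i}" for i in range(40)]
        links = GrantLinkSet({f"g{k}": list(rng.choice(docs, 6, replace=False)) for k in range(5)})
        coarse = Partition({d: i // 10 for i, d in enumerate(docs)}, set())
        fine = Partition({d: i // 5 for i, d in enumerate(docs)}, set())
        pg_c, h_c = herfindahl(links, coarse)
        pg_f, h_f = herfindahl(links, fine)
        for g, h_i in pg_c.items():
            touched = len({coarse.assignments[a] for a in links.links[g]})
            assert 1 / touched - 1e-12 <= h_i <= 1 + 1e-12
        assert h_f <= h_c + 1e-12


class TestPrecisionRecall:
    def test_single_cluster_all_linked(self):
        links = GrantLinkSet({"g": ["a", "b", "c", "d"]})
        part = Partition({d: 0 for d in "abcd"}, set())
        curve = precision_recall(links, part)
        assert curve.precision.tolist() == [1.0]
        assert curve.recall.tolist() == [1.0]
        assert curve.max_f1 == pytest.approx(1.0)

    def test_two_cluster_hand_walk(self):
        links = GrantLinkSet({"g": ["a", "b", "c", "d"]})
        assignments = {d: 0 for d in "abcd"}
        assignments.update({d: 1 for d in "wxyz"})
        curve = precision_recall(links, Partition(assignments, set()))
        assert curve.precision.tolist() == [1.0, 0.5]
        assert curve.recall.tolist() == [1.0, 1.0]
        assert curve.max_f1 == pytest.approx(1.0)

    def test_f1_formula_at_every_point(self, small_synth):
        _, records, truth, links = small_synth
        curve = precision_recall(links, truth)
        np.testing.assert_allclose(
            curve.f1,
            2 * curve.precision * curve.recall / (curve.precision + curve.recall),
        )

    def test_precision_weakly_decreasing(self, small_synth):
        _, records, truth, links = small_synth
        curve = precision_recall(links, truth)
        assert (np.diff(curve.recall) >= -1e-12).all()
        # clusters are ordered by linked fraction, so precision cannot rise
        assert (np.diff(curve.precision) <= 1e-12).all()

    def test_zero_links_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(GrantLinkSet({}), Partition({"a": 0}, set()))

    def test_grant_links_tsv_roundtrip(self, tmp_path):
        links = GrantLinkSet({"g1": ["a", "b"], "g2": ["c"]})
        links.write(tmp_path / "grants.tsv")
        back = GrantLinkSet.read(tmp_path / "grants.tsv")
        assert back.links == links.links


class TestCoherenceReport:
    def test_weighted_average_recomputable(self, small_synth):
        _, records, truth, _ = small_synth
        from litsim.pipeline import RunConfig, _build_matrix

        tdm = _build_matrix(records, RunConfig(source="ta", min_df=1, force=True))
        baseline = random_baseline(
            tdm.counts.T, sorted({n for n in truth.sizes().values()}), n_samples=30, seed=0
        )
        report = coherence_report(tdm, truth, baseline)
        num = sum(n * c for _, n, _, _, c in report.rows)
        den = sum(n for _, n, _, _, c in report.rows)
        assert report.weighted_coherence == pytest.approx(num / den, abs=1e-12)

    def test_true_partition_beats_random_relabeling(self, small_synth):
        """Planted structure scores higher weighted coherence and higher H
        than a size-matched random relabeling in >= 9/10 seeds."""
        config, records, truth, links = small_synth
        from litsim.pipeline import RunConfig, _build_matrix

        tdm = _build_matrix(records, RunConfig(source="ta", min_df=1, force=True))
        sizes = sorted(set(truth.sizes().values()))
        baseline = random_baseline(tdm.counts.T, sizes, n_samples=40, seed=0)
        coh_true = coherence_report(tdm, truth, baseline).weighted_coherence
        _, h_true = herfindahl(links, truth)
        docs = sorted(truth.assignments)
        labels = [truth.assignments[d] for d in docs]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shuffled = list(labels)
            rng.shuffle(shuffled)
            rand_part = Partition(dict(zip(docs, shuffled)), set())
            coh_rand = coherence_report(tdm, rand_part, baseline).weighted_coherence
            _, h_rand = herfindahl(links, rand_part)
            wins += (coh_true > coh_rand) and (h_true > h_rand)
        assert wins >= 9
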