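"""Cluster-quality metrics.

Two families of measures compare cluster solutions:

* Textual coherence.  For each cluster, the Jensen-Shannon divergence (JSD,
  log base 2, range [0,1]) between every member document's word distribution
  p and the cluster's word distribution q is averaged; the cluster JSD is
  normalized against the expected JSD of random document sets of the same
  size, and the per-cluster coherence values are combined as a size-weighted
  average.  Higher coherence = textually tighter clusters.

* Concentration.  Grant-to-article links provide an independent signal: the
  articles acknowledging one grant should concentrate in few clusters.  A
  per-grant Herfindahl index H_i = sum_j (n_ij / n_i)^2 is averaged over
  grants weighted by n_i; and a cluster-ordered precision-recall curve yields
  max F1 = max 2PR/(P+R) and Pr80 (precision at recall 0.80).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import rel_entr

from .cluster import Partition
from .corpus import TermDocumentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "jsd",
    "cluster_coherence",
    "random_baseline",
    "BaselineInterpolator",
    "CoherenceReport",
    "coherence_report",
    "GrantLinkSet",
    "herfindahl",
    "PrCurve",
    "precision_recall",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Jensen-Shannon coherence
# ---------------------------------------------------------------------------

def jsd(p: np.ndarray, q: np.ndarray, base: float = 2.0, tol: float = 1e-6) -> float:
    """Jensen-Shannon divergence (1/2)KL(p||m) + (1/2)KL(q||m), m=(p+q)/2.

    Log base 2 by default so the range is [0, 1]; 0 log 0 is taken as 0.
    Inputs must be nonnegative and sum to 1 within ``tol``.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must share a (zero-padded) vocabulary")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or abs(v.sum() - 1.0) > tol:
            raise ValueError(f"{name} is not a probability distribution")
    m = 0.5 * (p + q)
    val = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(val / math.log(base))


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return counts / sums


def _mean_doc_to_cluster_jsd(counts: np.ndarray, base: float = 2.0) -> float:
    """Mean JSD of each document row against the cluster distribution.

    ``counts`` is a dense docs x vocab count array; the cluster distribution
    q is the normalized column sum (each document included in its own
    cluster's distribution).  Empty documents are skipped with a warning.
    """
    counts = np.asarray(counts, dtype=np.float64)
    nonempty = counts.sum(axis=1) > 0
    if not nonempty.all():
        logger.warning("%d empty documents skipped in cluster JSD", int((~nonempty).sum()))
    counts = counts[nonempty]
    if counts.shape[0] == 0:
        raise ValueError("cluster has no non-empty documents")
    q = counts.sum(axis=0)
    q = q / q.sum()
    P = _row_normalize(counts)
    M = 0.5 * (P + q[None, :])
    per_doc = 0.5 * rel_entr(P, M).sum(axis=1) + 0.5 * rel_entr(
        np.broadcast_to(q, P.shape), M
    ).sum(axis=1)
    return float(per_doc.mean() / math.log(base))


def cluster_coherence(
    cluster_docs: np.ndarray,
    baseline: float,
    normalization: str = "relative",
) -> tuple[float, float]:
    """(JSD_i, Coh_i) for one cluster given its baseline JSD(rand)(n_i).

    Coh_i = (JSD(rand) - JSD_i) / JSD(rand) by default ("relative"); the
    "absolute" switch returns the plain difference JSD(rand) - JSD_i.  Both
    are monotone in JSD_i, so rankings at fixed cluster size agree.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    jsd_i = _mean_doc_to_cluster_jsd(cluster_docs)
    if normalization == "relative":
        coh = (baseline - jsd_i) / baseline
    elif normalization == "absolute":
        coh = baseline - jsd_i
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return jsd_i, coh


DEFAULT_BASELINE_SIZES = (2, 5, 10, 20, 50, 100, 200, 500)


def random_baseline(
    corpus_counts: sp.spmatrix | np.ndarray,
    sizes: Sequence[int],
    n_samples: int = 5000,
    seed: int = 0,
) -> dict[int, float]:
    """JSD(rand): expected cluster JSD of random document sets per size.

    For each requested size, ``n_samples`` uniform random subsets of the
    corpus are drawn and their cluster JSD values averaged (full-scale
    reference: 5,000 samples; reduce for small studies).  Size 1 is 0 by
    definition.  Deterministic per seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    X = np.asarray(
        corpus_counts.todense() if sp.issparse(corpus_counts) else corpus_counts,
        dtype=np.float64,
    )
    n_docs = X.shape[0]
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for size in sorted(set(int(s) for s in sizes)):
        if size > n_docs:
            raise ValueError(f"baseline size {size} exceeds corpus of {n_docs}")
        if size == 1:
            out[1] = 0.0
            continue
        vals = []
        for _ in range(n_samples):
            idx = rng.choice(n_docs, size=size, replace=False)
            vals.append(_mean_doc_to_cluster_jsd(X[idx]))
        out[size] = float(np.mean(vals))
    return out


class BaselineInterpolator:
    """Linear interpolation of JSD(rand) between sampled sizes."""

    def __init__(self, baseline: Mapping[int, float]):
        if not baseline:
            raise ValueError("empty baseline map")
        items = sorted(baseline.items())
        self.sizes = np.array([s for s, _ in items], dtype=np.float64)
        self.values = np.array([v for _, v in items], dtype=np.float64)

    def __call__(self, size: int) -> float:
        return float(np.interp(size, self.sizes, self.values))


@dataclass
class CoherenceReport:
    """Per-cluster JSD/coherence rows plus the size-weighted corpus value."""

    rows: list[tuple[int, int, float, float, float]]  # (label, n, JSD, baseline, Coh)
    weighted_coherence: float
    normalization: str = "relative"
    jsd_log_base: float = 2.0

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# cluster\tn\tjsd\tbaseline\tcoherence\n")
            for lab, n, j, b, c in self.rows:
                fh.write(f"{lab}\t{n}\t{j:.6f}\t{b:.6f}\t{c:.6f}\n")
            fh.write(
                f"# weighted_coherence\t{self.weighted_coherence:.6f}"
                f"\t(normalization={self.normalization},"
                f" jsd_log_base={self.jsd_log_base:g})\n"
            )


def coherence_report(
    tdm: TermDocumentMatrix,
    partition: Partition,
    baseline: Callable[[int], float] | Mapping[int, float],
    normalization: str = "relative",
) -> CoherenceReport:
    """Score every cluster of a partition and combine Coh = sum n_i Coh_i / sum n_i."""
    if isinstance(baseline, Mapping):
        baseline = BaselineInterpolator(baseline)
    dindex = tdm.doc_index()
    X = np.asarray(tdm.counts.T.todense(), dtype=np.float64)  # docs x vocab
    rows = []
    total_n = 0
    total = 0.0
    for lab, members in sorted(partition.clusters().items()):
        idx = [dindex[d] for d in members]
        n_i = len(idx)
        b = baseline(n_i)
        jsd_i, coh_i = cluster_coherence(X[idx], b, normalization)
        rows.append((lab, n_i, jsd_i, b, coh_i))
        total += n_i * coh_i
        total_n += n_i
    if total_n == 0:
        raise ValueError("partition has no assigned documents")
    return CoherenceReport(rows, total / total_n, normalization)


# ---------------------------------------------------------------------------
# Grant-linkage concentration
# ---------------------------------------------------------------------------

@dataclass
class GrantLinkSet:
    """Grant -> article links (one link per (grant, article) pair)."""

    links: dict[str, list[str]]
    min_articles: int = 4

    def filtered(self) -> dict[str, list[str]]:
        """Grants that produced at least ``min_articles`` articles."""
        return {g: arts for g, arts in self.links.items() if len(arts) >= self.min_articles}

    @property
    def n_links(self) -> int:
        return sum(len(a) for a in self.filtered().values())

    @classmethod
    def read(cls, path: str | Path, min_articles: int = 4) -> "GrantLinkSet":
        """TSV (grant_id, doc_id)."""
        links: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                g, d = line.split("\t")
                links.setdefault(g, []).append(d)
        return cls(links, min_articles)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for g in sorted(self.links):
                for d in self.links[g]:
                    fh.write(f"{g}\t{d}\n")


def herfindahl(
    links: GrantLinkSet, partition: Partition
) -> tuple[dict[str, float], float]:
    """Per-grant H_i = sum_j (n_ij/n_i)^2 and the weighted mean H.

    Grants below the link set's minimum-articles threshold are excluded;
    articles unassigned in the partition do not count toward n_i.  H is the
    n_i-weighted average over grants.
    """
    per_grant: dict[str, float] = {}
    num = 0.0
    den = 0.0
    for grant, articles in sorted(links.filtered().items()):
        labs = [partition.assignments[a] for a in articles if a in partition.assignments]
        n_i = len(labs)
        if n_i == 0:
            logger.warning("grant %s has no assigned articles; dropped", grant)
            continue
        counts: dict[int, int] = {}
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
        h_i = sum((c / n_i) ** 2 for c in counts.values())
        per_grant[grant] = h_i
        num += n_i * h_i
        den += n_i
    if den == 0:
        raise ValueError("no grant has any assigned article")
    return per_grant, num / den


@dataclass
class PrCurve:
    """Cluster-ordered cumulative precision-recall curve."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    pr80: float
    max_f1: float


def precision_recall(links: GrantLinkSet, partition: Partition) -> PrCurve:
    """Precision-recall over clusters ordered by linked-article fraction.

    "Correct" articles are those linked to any retained grant.  Clusters are
    sorted by descending fraction of correct articles (ties: larger cluster
    first, then label); walking down the list, recall is the cumulative count
    of links whose article has been covered divided by all links in the
    retained set, and precision is cumulative correct articles over cumulative
    articles.  Pr80 is the precision linearly interpolated at recall 0.80
    (NaN when the curve never reaches it); max F1 = max 2PR/(P+R) over points.
    """
    filtered = links.filtered()
    if not filtered:
        raise ValueError("no grants pass the minimum-articles filter")
    if not partition.assignments:
        raise ValueError("empty partition")
    links_per_article: dict[str, int] = {}
    for arts in filtered.values():
        for a in arts:
            links_per_article[a] = links_per_article.get(a, 0) + 1
    total_links = sum(links_per_article.values())
    clusters = partition.clusters()
    stats = []
    for lab, members in clusters.items():
        correct = [d for d in members if d in links_per_article]
        frac = len(correct) / len(members)
        link_count = sum(links_per_article[d] for d in correct)
        stats.append((frac, len(members), lab, len(correct), link_count))
    stats.sort(key=lambda t: (-t[0], -t[1], t[2]))
    P, R, F = [], [], []
    cum_docs = cum_correct = cum_links = 0
    for frac, n, lab, n_correct, link_count in stats:
        cum_docs += n
        cum_correct += n_correct
        cum_links += link_count
        p = cum_correct / cum_docs
        r = cum_links / total_links
        P.append(p)
        R.append(r)
        F.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    P, R, F = np.array(P), np.array(R), np.array(F)
    if R[-1] >= 0.80:
        pr80 = float(np.interp(0.80, np.concatenate([[0.0], R]), np.concatenate([[P[0]], P])))
    else:
        logger.warning("recall never reaches 0.80; Pr80 undefined")
        pr80 = float("nan")
    return PrCurve(P, R, F, pr80, float(F.max()))


def write_concentration_report(
    per_grant: Mapping[str, float],
    h: float,
    curve: PrCurve,
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# grant\therfindahl\n")
        for g in sorted(per_grant):
            fh.write(f"{g}\t{per_grant[g]:.6f}\n")
        fh.write(f"# weighted_H\t{h:.6f}\n")
        fh.write(f"# max_F1\t{curve.max_f1:.6f}\n")
        fh.write(f"# Pr80\t{curve.pr80:.6f}\n")
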