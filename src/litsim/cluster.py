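"""Consensus clustering of the top-n similarity graph.

The protocol: a stochastic base clusterer (by default, a seeded force-directed
2-D layout with longest-edge cutting followed by average-link agglomeration on
layout proximity, split by surviving-edge connectivity) is run R times (default
10) with different seeds.  Document pairs co-clustered in at least
``membership_threshold`` of the R runs (default 4) enter the consensus
solution; two multi-document clusters may only be merged through pairs
co-clustered in at least ``join_threshold`` runs (default 7).  Documents in no
sufficiently stable pair are left unassigned.  Finally clusters below the
minimum size (default 25) are merged into their most similar neighbor cluster.

The base clusterer is a pluggable contract: any callable
``(SimilarityEdgeList, seed) -> Partition`` that is deterministic per seed and
stochastic across seeds can stand in for the default.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as hierarchy
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from .similarity import SimilarityEdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ConsensusCounts",
    "base_cluster",
    "consensus_counts",
    "consensus_cluster",
    "enforce_min_cluster_size",
    "coverage",
    "cluster_documents",
]


@dataclass
class Partition:
    """Cluster assignments for part of a corpus; unassigned docs explicit."""

    assignments: dict[str, int]
    unassigned: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & self.unassigned
        if overlap:
            raise ValueError(f"docs both assigned and unassigned: {sorted(overlap)[:5]}")

    @property
    def n_docs(self) -> int:
        return len(self.assignments) + len(self.unassigned)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for doc, lab in self.assignments.items():
            out[lab].append(doc)
        return {lab: sorted(members) for lab, members in out.items()}

    def sizes(self) -> dict[int, int]:
        return {lab: len(m) for lab, m in self.clusters().items()}

    def canonical(self) -> "Partition":
        """Relabel clusters 0,1,... by their smallest member id (for
        label-invariant comparisons)."""
        clusters = sorted(self.clusters().values(), key=lambda m: m[0])
        assignments = {doc: i for i, members in enumerate(clusters) for doc in members}
        return Partition(assignments, set(self.unassigned))


@dataclass
class ConsensusCounts:
    """Per-pair count of runs in which the pair was co-clustered."""

    counts: dict[tuple[str, str], int]
    n_runs: int
    all_docs: set[str]

    def __post_init__(self) -> None:
        for (a, b), c in self.counts.items():
            if a >= b:
                raise ValueError(f"unordered pair key ({a},{b})")
            if not (0 <= c <= self.n_runs):
                raise ValueError(f"count {c} outside [0, {self.n_runs}]")


# ---------------------------------------------------------------------------
# Base clusterer: force-directed layout + edge cutting + average link
# ---------------------------------------------------------------------------

def _fruchterman_reingold(
    n: int,
    edge_idx: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    iterations: int = 80,
) -> np.ndarray:
    """Seeded weighted Fruchterman-Reingold layout in the unit square."""
    pos = rng.random((n, 2))
    k = 1.0 / np.sqrt(n)
    w = weights / weights.max() if weights.max() > 0 else weights
    t0 = 0.1
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(dist, 1.0)
        # repulsion between every pair
        disp = (delta / dist[:, :, None] ** 2).sum(axis=1) * k * k
        # attraction along weighted edges
        ed = pos[edge_idx[:, 0]] - pos[edge_idx[:, 1]]
        edist = np.linalg.norm(ed, axis=1, keepdims=True)
        edist[edist == 0] = 1e-9
        force = ed / edist * (edist**2) * w[:, None] / k
        np.add.at(disp, edge_idx[:, 0], -force)
        np.add.at(disp, edge_idx[:, 1], force)
        length = np.linalg.norm(disp, axis=1, keepdims=True)
        length[length == 0] = 1e-9
        t = t0 * (1.0 - it / iterations) + 1e-3
        pos += disp / length * np.minimum(length, t)
    return pos


def base_cluster(
    edges: SimilarityEdgeList,
    seed: int,
    layout_iterations: int = 80,
    cut_fraction: float = 0.15,
    merge_factor: float = 2.0,
) -> Partition:
    """One stochastic preliminary solution over the similarity graph.

    Seeded random initial positions feed a weighted force-directed layout; the
    longest ``cut_fraction`` of edges (by layout distance) are cut; surviving
    nodes are agglomerated by average linkage on 2-D positions, the dendrogram
    cut at ``merge_factor`` times the median surviving-edge length; clusters
    are finally split along surviving-edge connected components.  Deterministic
    for a fixed seed.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    docs = sorted(edges.doc_ids())
    index = {d: i for i, d in enumerate(docs)}
    n = len(docs)
    edge_idx = np.array([(index[a], index[b]) for a, b, _ in edges.edges])
    weights = np.array([s for _, _, s in edges.edges], dtype=np.float64)
    rng = np.random.default_rng(seed)
    if n == 2:
        return Partition({docs[0]: 0, docs[1]: 0}, set())
    pos = _fruchterman_reingold(n, edge_idx, weights, rng, layout_iterations)
    lengths = np.linalg.norm(pos[edge_idx[:, 0]] - pos[edge_idx[:, 1]], axis=1)
    n_cut = int(np.floor(cut_fraction * len(lengths)))
    keep = np.ones(len(lengths), dtype=bool)
    if n_cut > 0:
        keep[np.argsort(-lengths)[:n_cut]] = False
    surv_len = lengths[keep]
    t = merge_factor * float(np.median(surv_len)) if surv_len.size else 0.0
    Z = hierarchy.linkage(pdist(pos), method="average")
    labels = hierarchy.fcluster(Z, t=max(t, 1e-12), criterion="distance")
    # split average-link clusters along surviving-edge connectivity
    rows = edge_idx[keep][:, 0]
    cols = edge_idx[keep][:, 1]
    same = labels[rows] == labels[cols]
    adj = sp.coo_matrix(
        (np.ones(int(same.sum())), (rows[same], cols[same])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    assignments = {docs[i]: int(comp[i]) for i in range(n)}
    return Partition(assignments, set()).canonical()


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_counts(partitions: Sequence[Partition]) -> ConsensusCounts:
    """Count, per unordered pair, in how many runs both docs share a label."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    counts: Counter[tuple[str, str]] = Counter()
    all_docs: set[str] = set()
    for part in partitions:
        all_docs |= set(part.assignments) | part.unassigned
        for members in part.clusters().values():
            for a, b in itertools.combinations(members, 2):
                counts[(a, b)] += 1
    return ConsensusCounts(dict(counts), len(partitions), all_docs)


def consensus_cluster(
    counts: ConsensusCounts,
    membership_threshold: int = 4,
    join_threshold: int = 7,
) -> Partition:
    """Re-cluster from pair co-occurrence counts.

    Pairs are processed in descending count order (ties by id).  A pair with
    count >= ``join_threshold`` may found a cluster, extend one, or merge two
    existing clusters.  A pair with membership_threshold <= count <
    join_threshold may found a cluster or attach an unassigned document, but
    never merges two existing clusters.  Documents in no pair with count >=
    membership_threshold stay unassigned.
    """
    if membership_threshold > join_threshold:
        raise ValueError("membership_threshold must be <= join_threshold")
    ordered = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    doc_cluster: dict[str, int] = {}
    clusters: dict[int, set[str]] = {}
    next_label = 0
    for (a, b), c in ordered:
        if c < membership_threshold:
            break
        ca, cb = doc_cluster.get(a), doc_cluster.get(b)
        if ca is None and cb is None:
            clusters[next_label] = {a, b}
            doc_cluster[a] = doc_cluster[b] = next_label
            next_label += 1
        elif ca is None or cb is None:
            lab = cb if ca is None else ca
            doc = a if ca is None else b
            clusters[lab].add(doc)
            doc_cluster[doc] = lab
        elif ca != cb:
            if c >= join_threshold:
                src, dst = (ca, cb) if len(clusters[ca]) < len(clusters[cb]) else (cb, ca)
                for doc in clusters.pop(src):
                    doc_cluster[doc] = dst
                    clusters[dst].add(doc)
            # below join threshold: two existing clusters are never merged
    unassigned = counts.all_docs - set(doc_cluster)
    return Partition(doc_cluster, unassigned).canonical()


def enforce_min_cluster_size(
    partition: Partition,
    edges: SimilarityEdgeList,
    min_size: int = 25,
) -> Partition:
    """Merge undersized clusters into their most similar cluster.

    Repeatedly takes the smallest cluster below ``min_size`` and merges it into
    the cluster with the highest mean retained-edge weight between members
    (ties by label).  An undersized cluster with no edge to any other cluster
    stays as it is (logged).  Coverage never decreases.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    assignments = dict(partition.assignments)
    edge_map = edges.to_dict()
    stuck: set[int] = set()
    while True:
        clusters = defaultdict(list)
        for doc, lab in assignments.items():
            clusters[lab].append(doc)
        small = [
            (len(m), lab)
            for lab, m in clusters.items()
            if len(m) < min_size and lab not in stuck
        ]
        if not small or len(clusters) < 2:
            break
        _, lab = min(small)
        members = set(clusters[lab])
        weight_sum: Counter[int] = Counter()
        weight_n: Counter[int] = Counter()
        for (a, b), s in edge_map.items():
            a_in, b_in = a in members, b in members
            if a_in == b_in:
                continue
            other = b if a_in else a
            lab_other = assignments.get(other)
            if lab_other is None or lab_other == lab:
                continue
            weight_sum[lab_other] += s
            weight_n[lab_other] += 1
        if not weight_n:
            logger.warning("cluster %s (<%d docs) has no edges to other clusters", lab, min_size)
            stuck.add(lab)
            continue
        best = max(weight_n, key=lambda lo: (weight_sum[lo] / weight_n[lo], -lo))
        for doc in members:
            assignments[doc] = best
    return Partition(assignments, set(partition.unassigned)).canonical()


def coverage(partition: Partition) -> float:
    """Fraction of the corpus assigned to any cluster."""
    total = partition.n_docs
    if total == 0:
        raise ValueError("empty corpus")
    return len(partition.assignments) / total


def cluster_documents(
    edges: SimilarityEdgeList,
    n_runs: int = 10,
    seed: int = 0,
    membership_threshold: int = 4,
    join_threshold: int = 7,
    min_size: int = 25,
    base: Callable[[SimilarityEdgeList, int], Partition] | None = None,
) -> Partition:
    """Full protocol: R base runs -> pair counts -> consensus -> min size."""
    base = base or base_cluster
    runs = [base(edges, seed + r) for r in range(n_runs)]
    counts = consensus_counts(runs)
    part = consensus_cluster(counts, membership_threshold, join_threshold)
    return enforce_min_cluster_size(part, edges, min_size)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_partition(partition: Partition, path: str | Path) -> None:
    """TSV (doc_id, cluster_label); unassigned docs get an empty label."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in sorted(partition.assignments):
            fh.write(f"{doc}\t{partition.assignments[doc]}\n")
        for doc in sorted(partition.unassigned):
            fh.write(f"{doc}\t\n")


def read_partition(path: str | Path) -> Partition:
    assignments: dict[str, int] = {}
    unassigned: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc, lab = line.split("\t")
            if lab == "":
                unassigned.add(doc)
            else:
                assignments[doc] = int(lab)
    return Partition(assignments, unassigned)


def write_consensus_counts(counts: ConsensusCounts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), c in sorted(counts.counts.items()):
            fh.write(f"{a}\t{b}\t{c}\n")
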