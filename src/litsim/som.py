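"""Self-organizing map branch (MeSH data source).

A rectangular grid of neurons, each holding a continuous weight vector in
term space, is trained online: every presented document vector is matched to
its best neuron by cosine similarity, and that neuron plus its grid
neighborhood (Gaussian over grid distance, shrinking diameter) is pulled
toward the document.  After training each document is assigned to its best
matching neuron, and grid-adjacent under-populated neuron groups are merged
greedily until every cluster holds at least ``min_docs`` documents, giving a
full-coverage partition.

Full-scale reference configuration: 275x275 neurons over the 2,300 most
frequent terms; tests run far smaller grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .cluster import Partition
from .corpus import TermDocumentMatrix

logger = logging.getLogger(__name__)

__all__ = ["SomGrid", "top_m_term_vectors", "som_train", "som_assign", "som_assign_and_merge"]


@dataclass
class SomGrid:
    rows: int = 10
    cols: int = 10
    epochs: int = 10
    initial_diameter: float | None = None  # defaults to max(rows, cols) / 2
    initial_lr: float = 0.5
    final_lr: float = 0.02
    seed: int = 0
    weights: np.ndarray | None = None  # (rows*cols) x dim, set by training

    def neuron_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)


def top_m_term_vectors(tdm: TermDocumentMatrix, m: int | None = 2300) -> np.ndarray:
    """Dense docs x terms matrix restricted to the ``m`` most frequent terms
    (by corpus count; full-scale reference m = 2,300)."""
    counts = tdm.counts
    if m is not None and m < tdm.n_terms:
        totals = np.asarray(counts.sum(axis=1)).ravel()
        keep = np.sort(np.argsort(-totals)[:m])
        counts = counts[keep, :]
    return np.asarray(counts.T.todense(), dtype=np.float64)


def _best_matching(weights: np.ndarray, x: np.ndarray) -> int:
    """Index of the neuron with the highest cosine similarity to x."""
    wn = np.linalg.norm(weights, axis=1)
    xn = np.linalg.norm(x)
    denom = wn * (xn if xn > 0 else 1.0)
    denom[denom == 0] = 1e-12
    return int(np.argmax(weights @ x / denom))


def som_train(vectors: np.ndarray, grid: SomGrid) -> SomGrid:
    """Train the grid on document vectors (rows of ``vectors``).

    Randomly seeded weights; per epoch, every document is presented in a
    seeded random order; neighborhood diameter and learning rate decay
    linearly across epochs.  Deterministic for a fixed seed.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty 2-D document-vector array")
    n_docs, dim = X.shape
    rng = np.random.default_rng(grid.seed)
    n_neurons = grid.rows * grid.cols
    weights = rng.random((n_neurons, dim))
    coords = grid.neuron_coords()
    sigma0 = grid.initial_diameter if grid.initial_diameter is not None else max(grid.rows, grid.cols) / 2.0
    total_steps = grid.epochs
    for epoch in range(grid.epochs):
        frac = epoch / max(total_steps - 1, 1)
        sigma = max(sigma0 * (1.0 - frac), 0.5)
        lr = grid.initial_lr + (grid.final_lr - grid.initial_lr) * frac
        for i in rng.permutation(n_docs):
            x = X[i]
            bmu = _best_matching(weights, x)
            gd2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / (2.0 * sigma * sigma))
            active = h > 1e-4
            weights[active] += lr * h[active, None] * (x - weights[active])
    out = SomGrid(**{**grid.__dict__})
    out.weights = weights
    return out


def som_assign(vectors: np.ndarray, grid: SomGrid) -> np.ndarray:
    """Best-matching neuron index per document (cosine similarity)."""
    if grid.weights is None:
        raise ValueError("grid is untrained")
    X = np.asarray(vectors, dtype=np.float64)
    W = grid.weights
    wn = np.linalg.norm(W, axis=1)
    wn[wn == 0] = 1e-12
    xn = np.linalg.norm(X, axis=1)
    xn[xn == 0] = 1e-12
    sims = (X @ W.T) / xn[:, None] / wn[None, :]
    return np.argmax(sims, axis=1)


def quantization_error(vectors: np.ndarray, grid: SomGrid) -> float:
    """Mean (1 - cosine) of documents to their best-matching neuron."""
    if grid.weights is None:
        raise ValueError("grid is untrained")
    X = np.asarray(vectors, dtype=np.float64)
    W = grid.weights
    wn = np.linalg.norm(W, axis=1)
    wn[wn == 0] = 1e-12
    xn = np.linalg.norm(X, axis=1)
    xn[xn == 0] = 1e-12
    sims = (X @ W.T) / xn[:, None] / wn[None, :]
    return float((1.0 - sims.max(axis=1)).mean())


def som_assign_and_merge(
    vectors: np.ndarray,
    grid: SomGrid,
    doc_ids: Sequence[str],
    min_docs: int = 25,
) -> Partition:
    """Assign docs to best neurons, then merge adjacent small neuron groups.

    Groups start as single occupied neurons.  Greedily, the smallest group
    below ``min_docs`` is merged into the 4-neighborhood-adjacent group whose
    mean weight vector has the highest cosine with its own (groups with no
    adjacent group fall back to the nearest occupied group by Manhattan grid
    distance).  Always yields full coverage; a corpus smaller than
    ``min_docs`` collapses to a single cluster.
    """
    if grid.weights is None:
        raise ValueError("grid is untrained")
    doc_ids = list(doc_ids)
    bmu = som_assign(vectors, grid)
    n_docs = len(doc_ids)
    if n_docs < min_docs:
        return Partition({d: 0 for d in doc_ids}, set())
    coords = grid.neuron_coords().astype(int)
    # group id per occupied neuron; groups are sets of neuron indices
    occupied = sorted(set(int(b) for b in bmu))
    group_of = {nn: gi for gi, nn in enumerate(occupied)}
    groups: dict[int, set[int]] = {gi: {nn} for nn, gi in group_of.items()}
    docs_in: dict[int, int] = {gi: 0 for gi in groups}
    for b in bmu:
        docs_in[group_of[int(b)]] += 1

    def group_mean_weight(gi: int) -> np.ndarray:
        return grid.weights[sorted(groups[gi])].mean(axis=0)

    def adjacent_groups(gi: int) -> set[int]:
        out: set[int] = set()
        for nn in groups[gi]:
            r, c = coords[nn]
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < grid.rows and 0 <= c2 < grid.cols:
                    nb = r2 * grid.cols + c2
                    if nb in group_of and group_of[nb] != gi:
                        out.add(group_of[nb])
        return out

    while True:
        small = [(n, gi) for gi, n in docs_in.items() if n < min_docs]
        if not small or len(groups) < 2:
            break
        _, gi = min(small)
        cands = adjacent_groups(gi)
        if cands:
            mine = group_mean_weight(gi)
            mn = np.linalg.norm(mine) or 1e-12

            def cos_to(gj: int) -> float:
                w = group_mean_weight(gj)
                return float(mine @ w / (mn * (np.linalg.norm(w) or 1e-12)))

            target = max(sorted(cands), key=cos_to)
        else:
            # isolated group: nearest occupied group by Manhattan grid distance
            best_d, target = None, None
            for gj in sorted(groups):
                if gj == gi:
                    continue
                d = min(
                    abs(coords[a][0] - coords[b][0]) + abs(coords[a][1] - coords[b][1])
                    for a in groups[gi]
                    for b in groups[gj]
                )
                if best_d is None or d < best_d:
                    best_d, target = d, gj
        for nn in groups.pop(gi):
            group_of[nn] = target
        groups[target] |= set()
        groups[target] = {nn for nn, g in group_of.items() if g == target}
        docs_in[target] += docs_in.pop(gi)

    labels = sorted(groups)
    relabel = {gi: i for i, gi in enumerate(labels)}
    assignments = {
        doc_ids[i]: relabel[group_of[int(bmu[i])]] for i in range(n_docs)
    }
    return Partition(assignments, set()).canonical()


def write_grid(grid: SomGrid, path: str | Path) -> None:
    """TSV of neuron row, col, weight vector components."""
    if grid.weights is None:
        raise ValueError("grid is untrained")
    with open(path, "w", encoding="utf-8") as fh:
        for idx in range(grid.rows * grid.cols):
            r, c = divmod(idx, grid.cols)
            vec = "\t".join(f"{v:.6g}" for v in grid.weights[idx])
            fh.write(f"{r}\t{c}\t{vec}\n")
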