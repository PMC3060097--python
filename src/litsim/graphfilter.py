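"""Top-n similarity filtering.

A dense or over-long similarity matrix is reduced to the edge file the
clustering step consumes.  Each document contributes between ``min_edges``
and ``max_edges`` of its strongest neighbors; how many is decided by where
log(mean of its top-15 similarities) sits between the corpus minimum and
maximum of that statistic.  Documents that are similar to many others thus
contribute more edges than documents that are similar to nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .similarity import SimilarityEdgeList

logger = logging.getLogger(__name__)

__all__ = ["TopNConfig", "top_n_filter", "matrix_to_neighbor_lists"]


@dataclass
class TopNConfig:
    top_window: int = 15   # how many top similarities enter the average
    min_edges: int = 5
    max_edges: int = 15

    def __post_init__(self) -> None:
        if not (self.min_edges <= self.max_edges <= self.top_window):
            raise ValueError("require min_edges <= max_edges <= top_window")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def top_n_filter(
    per_doc_similarities: Mapping[str, Sequence[tuple[str, float]]],
    config: TopNConfig | None = None,
) -> SimilarityEdgeList:
    """Build the top-n edge list from per-document neighbor similarity lists.

    For each document the mean ``a`` of its top-``top_window`` similarities is
    taken; s = log(a) (documents with a <= 0 get ``min_edges``) is min-max
    rescaled across the corpus onto [min_edges, max_edges] with half-up
    rounding, giving that document's edge budget n_e.  Its n_e
    highest-similarity neighbors are emitted (fewer when fewer exist); all
    contributions are merged and unordered pairs de-duplicated, keeping the
    larger similarity when the two orientations disagree (asymmetric
    measures).  Edge weights are never rescaled.
    """
    config = config or TopNConfig()
    sorted_lists: dict[str, list[tuple[str, float]]] = {}
    log_avg: dict[str, float] = {}
    for doc, neigh in per_doc_similarities.items():
        ordered = sorted(neigh, key=lambda ts: (-ts[1], ts[0]))
        if not ordered:
            logger.warning("document %s has no neighbors; contributes nothing", doc)
            continue
        sorted_lists[doc] = ordered
        top = [s for _, s in ordered[: config.top_window]]
        a = float(np.mean(top))
        log_avg[doc] = math.log(a) if a > 0 else -math.inf

    finite = [v for v in log_avg.values() if math.isfinite(v)]
    lo = min(finite) if finite else 0.0
    hi = max(finite) if finite else 0.0
    span = hi - lo

    best: dict[tuple[str, str], float] = {}
    for doc, ordered in sorted_lists.items():
        s = log_avg[doc]
        if not math.isfinite(s):
            n_e = config.min_edges
        elif span == 0:
            # degenerate corpus: every document looks the same; keep the most
            n_e = config.max_edges
        else:
            frac = (s - lo) / span
            n_e = _round_half_up(config.min_edges + frac * (config.max_edges - config.min_edges))
            n_e = max(config.min_edges, min(config.max_edges, n_e))
        for tgt, sim in ordered[:n_e]:
            if tgt == doc:
                continue
            pair = (doc, tgt) if doc < tgt else (tgt, doc)
            if sim > best.get(pair, -1.0):
                best[pair] = sim
    return SimilarityEdgeList([(a, b, s) for (a, b), s in sorted(best.items())])


def matrix_to_neighbor_lists(
    sims: np.ndarray,
    doc_ids: Sequence[str],
    top_window: int = 15,
    min_similarity: float = 0.0,
) -> dict[str, list[tuple[str, float]]]:
    """Per-document top-``top_window`` neighbor lists from a dense doc x doc
    similarity matrix (self-similarities and values <= min_similarity dropped)."""
    n = len(doc_ids)
    if sims.shape != (n, n):
        raise ValueError("similarity matrix shape does not match doc_ids")
    out: dict[str, list[tuple[str, float]]] = {}
    for i, doc in enumerate(doc_ids):
        row = sims[i].copy()
        row[i] = -np.inf
        k = min(top_window, n - 1)
        if k <= 0:
            out[doc] = []
            continue
        idx = np.argpartition(-row, k - 1)[:k]
        pairs = [
            (doc_ids[j], float(row[j]))
            for j in idx
            if np.isfinite(row[j]) and row[j] > min_similarity
        ]
        pairs.sort(key=lambda ts: (-ts[1], ts[0]))
        out[doc] = pairs
    return out
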