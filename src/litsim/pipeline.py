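"""End-to-end benchmark runs: preprocess -> similarity -> filter -> cluster
-> validate, with every intermediate artifact written to a run directory.

A run is described by a :class:`RunConfig`: one similarity method, one data
source (``ta`` title/abstract words or ``mesh`` descriptors), and the stage
parameters.  Only the nine realized method/source combinations are accepted
unless ``force`` is set:

    tfidf-cosine x {mesh, ta}, lsa x {mesh, ta}, bm25 x {mesh, ta},
    som x mesh, topics x ta, pmra-proxy x ta

The summary mirrors the headline comparison columns: coverage, cluster
count, max cluster size, weighted coherence, Herfindahl, max F1 and Pr80.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .cluster import Partition, cluster_documents, coverage, write_partition
from .corpus import (
    DocumentRecord,
    build_term_document_matrix,
    clean_mesh_terms,
    default_stopwords,
    filter_corpus,
    reduce_vocabulary_for_topics,
    tokenize_title_abstract,
)
from .graphfilter import TopNConfig, matrix_to_neighbor_lists, top_n_filter
from .similarity import (
    Bm25Params,
    RankList,
    bm25_all_pairs,
    fit_topic_models,
    lsa_all_pairs,
    lsa_fit,
    pairwise_cosine,
    rank_lists_to_similarities,
    restrict_rank_lists,
    tfidf_transform,
    topic_all_pairs,
    write_edges,
)
from .som import SomGrid, som_assign_and_merge, som_train, top_m_term_vectors
from .validate import (
    DEFAULT_BASELINE_SIZES,
    GrantLinkSet,
    coherence_report,
    herfindahl,
    precision_recall,
    random_baseline,
    write_concentration_report,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "REALIZED_COMBINATIONS"]

REALIZED_COMBINATIONS = frozenset(
    {
        ("tfidf-cosine", "mesh"),
        ("tfidf-cosine", "ta"),
        ("lsa", "mesh"),
        ("lsa", "ta"),
        ("bm25", "mesh"),
        ("bm25", "ta"),
        ("som", "mesh"),
        ("topics", "ta"),
        ("pmra-proxy", "ta"),
    }
)


@dataclass
class RunConfig:
    method: str = "tfidf-cosine"
    source: str = "ta"  # "ta" | "mesh"
    seed: int = 0
    out_dir: str | Path | None = None
    force: bool = False
    # preprocessing
    min_df: int = 4
    apply_corpus_filter: bool = False
    # LSA
    lsa_k: int | None = None  # default 100 (ta) / 200 (mesh), capped by shape
    # BM25
    bm25_k1: float = 2.0
    bm25_b: float = 0.75
    bm25_idf_threshold: float | None = None  # default 2.0 (ta) / 1.5 (mesh)
    # topics
    topic_resolutions: tuple[int, ...] = (10, 20, 40)
    topic_iterations: int = 150
    topic_min_corpus_count: int = 50
    # SOM
    som_rows: int = 10
    som_cols: int = 10
    som_epochs: int = 10
    som_top_terms: int | None = 2300
    # filtering / clustering
    top_window: int = 15
    min_edges: int = 5
    max_edges: int = 15
    n_runs: int = 10
    membership_threshold: int = 4
    join_threshold: int = 7
    min_cluster_size: int = 25
    # validation
    baseline_samples: int = 200
    baseline_sizes: tuple[int, ...] = DEFAULT_BASELINE_SIZES
    coherence_normalization: str = "relative"

    def validate(self) -> None:
        if self.source not in ("ta", "mesh"):
            raise ValueError(f"unknown data source {self.source!r}")
        if (self.method, self.source) not in REALIZED_COMBINATIONS and not self.force:
            raise ValueError(
                f"{self.method}/{self.source} is not one of the nine realized "
                "combinations; pass force=True to run it anyway"
            )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _build_matrix(records: Sequence[DocumentRecord], config: RunConfig):
    if config.source == "ta":
        stop = default_stopwords()
        docs = {
            r.doc_id: tokenize_title_abstract(r.title, r.abstract, stop) for r in records
        }
        return build_term_document_matrix(docs, min_df=config.min_df, binary=False)
    docs = {}
    for r in records:
        pairs = (
            list(zip(r.mesh_terms, r.mesh_classes))
            if r.mesh_classes is not None
            else list(r.mesh_terms)
        )
        docs[r.doc_id] = clean_mesh_terms(pairs)
    return build_term_document_matrix(docs, min_df=config.min_df, binary=True)


def _similarity_matrix(tdm, config: RunConfig, rank_lists):
    method = config.method
    if method == "tfidf-cosine":
        sims = pairwise_cosine(tfidf_transform(tdm))
        np.fill_diagonal(sims, 0.0)
        return matrix_to_neighbor_lists(sims, tdm.doc_ids, config.top_window)
    if method == "lsa":
        k = config.lsa_k or (200 if config.source == "mesh" else 100)
        k = max(1, min(k, min(tdm.n_terms, tdm.n_docs) - 1))
        sims = lsa_all_pairs(lsa_fit(tfidf_transform(tdm), k))
        np.fill_diagonal(sims, 0.0)
        sims = np.clip(sims, 0.0, None)  # edges must be nonnegative
        return matrix_to_neighbor_lists(sims, tdm.doc_ids, config.top_window)
    if method == "bm25":
        thr = config.bm25_idf_threshold
        if thr is None:
            thr = 1.5 if config.source == "mesh" else 2.0
        params = Bm25Params(k1=config.bm25_k1, b=config.bm25_b, idf_threshold=thr)
        sims = bm25_all_pairs(tdm, params)
        return matrix_to_neighbor_lists(sims, tdm.doc_ids, config.top_window)
    if method == "topics":
        reduced, fraction = reduce_vocabulary_for_topics(
            tdm, min_corpus_count=config.topic_min_corpus_count
        )
        logger.info("topic vocabulary reduction retained %.1f%% of tokens", 100 * fraction)
        models = fit_topic_models(
            reduced,
            resolutions=config.topic_resolutions,
            iterations=config.topic_iterations,
            seed=config.seed,
        )
        sims = topic_all_pairs(models)
        return matrix_to_neighbor_lists(sims, tdm.doc_ids, config.top_window)
    if method == "pmra-proxy":
        if rank_lists is None:
            raise ValueError("pmra-proxy requires rank lists")
        restricted = restrict_rank_lists(rank_lists, set(tdm.doc_ids))
        return rank_lists_to_similarities(restricted)
    raise ValueError(f"unknown method {config.method!r}")


def run_pipeline(
    records: Sequence[DocumentRecord],
    config: RunConfig,
    grant_links: GrantLinkSet | None = None,
    rank_lists: Sequence[RankList] | None = None,
) -> dict:
    """Execute the full benchmark for one method/source combination.

    Returns the machine-readable summary; when ``config.out_dir`` is set, the
    edge file, partition, validation reports, config and summary are written
    there.  Identical configs and seeds produce identical artifacts.
    """
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.apply_corpus_filter:
        records = _stage("preprocess")(filter_corpus)(records)
    tdm = _stage("preprocess")(_build_matrix)(records, config)

    if config.method == "som":
        vectors = top_m_term_vectors(tdm, config.som_top_terms)
        grid = SomGrid(
            rows=config.som_rows,
            cols=config.som_cols,
            epochs=config.som_epochs,
            seed=config.seed,
        )
        grid = _stage("som-train")(som_train)(vectors, grid)
        partition = _stage("som-assign")(som_assign_and_merge)(
            vectors, grid, tdm.doc_ids, config.min_cluster_size
        )
        edges = None
    else:
        neighbor_lists = _stage("similarity")(_similarity_matrix)(tdm, config, rank_lists)
        edges = _stage("filter")(top_n_filter)(
            neighbor_lists,
            TopNConfig(config.top_window, config.min_edges, config.max_edges),
        )
        if out_dir:
            write_edges(edges, out_dir / "edges.tsv")
        partition = _stage("cluster")(cluster_documents)(
            edges,
            n_runs=config.n_runs,
            seed=config.seed,
            membership_threshold=config.membership_threshold,
            join_threshold=config.join_threshold,
            min_size=config.min_cluster_size,
        )
        missing = {r.doc_id for r in records} - set(partition.assignments) - partition.unassigned
        partition = Partition(partition.assignments, partition.unassigned | missing)

    if out_dir:
        write_partition(partition, out_dir / "partition.tsv")

    # validation always scores textual coherence on title/abstract words
    ta_config = RunConfig(**{**asdict(config), "source": "ta", "force": True})
    ta_tdm = tdm if config.source == "ta" else _build_matrix(records, ta_config)
    sizes = partition.sizes()
    max_size = max(sizes.values()) if sizes else 0
    baseline_sizes = sorted(
        {s for s in config.baseline_sizes if s <= ta_tdm.n_docs} | ({max_size} if max_size > 1 else set())
    )
    baseline = _stage("validate")(random_baseline)(
        ta_tdm.counts.T, baseline_sizes, n_samples=config.baseline_samples, seed=config.seed
    )
    report = _stage("validate")(coherence_report)(
        ta_tdm, partition, baseline, config.coherence_normalization
    )
    if out_dir:
        report.write(out_dir / "coherence.tsv")

    summary = {
        "method": config.method,
        "source": config.source,
        "seed": config.seed,
        "version": __version__,
        "n_docs": len(records),
        "coverage": coverage(partition),
        "n_clusters": len(sizes),
        "max_cluster_size": max_size,
        "coherence": report.weighted_coherence,
        "herfindahl": None,
        "max_f1": None,
        "pr80": None,
    }
    if grant_links is not None:
        per_grant, h = _stage("validate")(herfindahl)(grant_links, partition)
        curve = _stage("validate")(precision_recall)(grant_links, partition)
        summary["herfindahl"] = h
        summary["max_f1"] = curve.max_f1
        summary["pr80"] = None if math.isnan(curve.pr80) else curve.pr80
        if out_dir:
            write_concentration_report(per_grant, h, curve, out_dir / "concentration.tsv")
    if out_dir:
        cfg = asdict(config)
        cfg["out_dir"] = str(config.out_dir)
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
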