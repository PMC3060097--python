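"""Bibliographic records and MEDLINE-style text preprocessing.

This module owns the corpus-side plumbing of the benchmark: the record model
(one id/title/abstract/MeSH/grant tuple per document), the inclusion filter,
title+abstract tokenization, MeSH descriptor cleaning, and construction of the
sparse term-document count matrix that every similarity technique consumes.

Conventions
-----------
* Term-document matrices are stored terms x documents (rows are terms), as
  scipy CSR with integer counts; MeSH-source matrices are binary.
* Vocabulary order is lexicographic so matrix files are reproducible.
* Tokenization keeps apostrophes, strips contraction suffixes (including the
  possessive ``'s``), drops stopwords and pure digit runs.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "DocumentRecord",
    "Vocabulary",
    "TermDocumentMatrix",
    "filter_corpus",
    "tokenize_title_abstract",
    "clean_mesh_terms",
    "build_term_document_matrix",
    "reduce_vocabulary_for_topics",
    "load_stopwords",
    "default_stopwords",
    "research_stopwords",
    "read_records_jsonl",
    "write_records_jsonl",
    "write_matrix",
    "read_matrix",
]

# Contraction suffixes stripped from token tails; the root is kept, the suffix
# discarded.  "n't" must precede "'t" so "don't" -> "do", not "don".
_CONTRACTION_SUFFIXES = ("n't", "'t", "'s", "'re", "'ve", "'ll", "'d", "'m")

_DIGIT_RUN = re.compile(r"^[0-9]+$")


@dataclass(frozen=True)
class DocumentRecord:
    """One bibliographic record: the unit the whole pipeline operates on."""

    doc_id: str
    title: str
    abstract: str
    mesh_terms: tuple[str, ...] = ()
    mesh_classes: tuple[int, ...] | None = None
    grant_ids: tuple[str, ...] = ()
    year: int | None = None
    n_references: int | None = None

    def to_json(self) -> dict:
        d = {
            "doc_id": self.doc_id,
            "title": self.title,
            "abstract": self.abstract,
            "mesh_terms": list(self.mesh_terms),
            "grant_ids": list(self.grant_ids),
            "year": self.year,
            "n_references": self.n_references,
        }
        if self.mesh_classes is not None:
            d["mesh_classes"] = list(self.mesh_classes)
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "DocumentRecord":
        classes = d.get("mesh_classes")
        return cls(
            doc_id=str(d["doc_id"]),
            title=d.get("title", ""),
            abstract=d.get("abstract", ""),
            mesh_terms=tuple(d.get("mesh_terms", ())),
            mesh_classes=tuple(classes) if classes is not None else None,
            grant_ids=tuple(d.get("grant_ids", ())),
            year=d.get("year"),
            n_references=d.get("n_references"),
        )


@dataclass
class Vocabulary:
    """Ordered unique terms with per-term document frequencies d_i."""

    terms: list[str]
    doc_freq: np.ndarray  # number of documents containing each term

    def __post_init__(self) -> None:
        self.doc_freq = np.asarray(self.doc_freq, dtype=np.int64)
        if len(self.terms) != len(self.doc_freq):
            raise ValueError("terms and doc_freq lengths differ")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class TermDocumentMatrix:
    """Sparse term-by-document counts n_ij (rows = terms, columns = documents)."""

    vocabulary: Vocabulary
    doc_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.vocabulary), len(self.doc_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.vocabulary)} terms x {len(self.doc_ids)} docs"
            )

    @property
    def n_terms(self) -> int:
        return self.counts.shape[0]

    @property
    def n_docs(self) -> int:
        return self.counts.shape[1]

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def doc_index(self) -> dict[str, int]:
        return {d: j for j, d in enumerate(self.doc_ids)}

    def recompute_doc_freq(self) -> np.ndarray:
        """Per-term count of documents with a nonzero cell (definition of d_i)."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel().astype(np.int64)


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

def filter_corpus(
    records: Iterable[DocumentRecord],
    min_year: int = 2004,
    max_year: int = 2008,
    min_mesh: int = 5,
    min_refs: int = 5,
    waive_missing_refs: bool = False,
) -> list[DocumentRecord]:
    """Apply the corpus inclusion criteria.

    Keeps records with a non-empty abstract, year within [min_year, max_year],
    at least ``min_mesh`` MeSH terms and (when the reference count is known)
    at least ``min_refs`` references.  Records with an unknown reference count
    pass the reference test only if ``min_refs == 0`` or
    ``waive_missing_refs`` is set.
    """
    if min_mesh < 0 or min_refs < 0:
        raise ValueError("thresholds must be nonnegative")
    kept = []
    for rec in records:
        if not rec.abstract.strip() or not rec.title.strip():
            continue
        if rec.year is None or not (min_year <= rec.year <= max_year):
            continue
        if len(rec.mesh_terms) < min_mesh:
            continue
        if rec.n_references is None:
            if min_refs > 0 and not waive_missing_refs:
                continue
        elif rec.n_references < min_refs:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def _strip_contraction(token: str) -> str:
    for suf in _CONTRACTION_SUFFIXES:
        if token.endswith(suf) and len(token) > len(suf):
            return token[: -len(suf)]
    return token


def _is_punct(ch: str) -> bool:
    if ch == "'":
        return False
    return unicodedata.category(ch).startswith("P")


def tokenize_title_abstract(
    title: str,
    abstract: str,
    stopwords: frozenset[str] | set[str] | None = None,
) -> list[str]:
    """Tokenize a concatenated title+abstract.

    Steps, in order: NFKC-normalize and map right single quotes to the ASCII
    apostrophe; replace every punctuation character except the apostrophe with
    a space; lower-case; split on whitespace; strip contraction suffixes
    (keeping the root, discarding the suffix); drop stopwords and pure digit
    runs.  Token multiplicity and order are preserved.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    text = f"{title} {abstract}"
    text = unicodedata.normalize("NFKC", text).replace("’", "'")
    chars = [" " if _is_punct(c) else c for c in text]
    tokens = "".join(chars).lower().split()
    out = []
    for tok in tokens:
        tok = _strip_contraction(tok)
        tok = tok.strip("'")
        if not tok:
            continue
        if tok in stopwords:
            continue
        if _DIGIT_RUN.match(tok):
            continue
        out.append(tok)
    return out


# ---------------------------------------------------------------------------
# MeSH cleaning
# ---------------------------------------------------------------------------

def _load_term_file(name: str) -> frozenset[str]:
    text = resources.files("litsim.data").joinpath(name).read_text(encoding="utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_stopwords(path: str | Path) -> frozenset[str]:
    """One token per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(
        ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
    )


def default_stopwords() -> frozenset[str]:
    """The packaged 132-word MEDLINE stoplist."""
    return frozenset(t.lower() for t in _load_term_file("medline_stopwords.txt"))


def research_stopwords() -> frozenset[str]:
    """Curated low-content research-prose words (optional second stoplist)."""
    return frozenset(t.lower() for t in _load_term_file("research_stopwords.txt"))


def _default_class34() -> frozenset[str]:
    return _load_term_file("mesh_check_tags.txt") | _load_term_file("mesh_geographic.txt")


def clean_mesh_terms(
    raw_terms: Sequence[str | tuple[str, int | None]],
    check_tag_list: frozenset[str] | None = None,
) -> list[str]:
    """Normalize raw MeSH descriptor strings.

    Drops '/qualifier' suffixes, removes Class 3 (check tags) and Class 4
    (geographic) descriptors, strips leading '*' emphasis markers, and
    de-duplicates while preserving order.  Terms may come as bare strings or
    (term, class_tag) pairs; when no class tag is available the packaged
    check-tag/geographic fallback list decides removal.
    """
    if check_tag_list is None:
        check_tag_list = _default_class34()
    seen: set[str] = set()
    out: list[str] = []
    for item in raw_terms:
        if isinstance(item, tuple):
            term, cls = item
        else:
            term, cls = item, None
        term = term.split("/", 1)[0].lstrip("*").strip()
        if not term:
            continue
        if cls in (3, 4):
            continue
        if cls is None and term in check_tag_list:
            continue
        if term in seen:
            continue
        seen.add(term)
        out.append(term)
    return out


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def build_term_document_matrix(
    tokenized_docs: Mapping[str, Sequence[str]],
    min_df: int = 4,
    binary: bool = False,
) -> TermDocumentMatrix:
    """Count tokens per document into a sparse terms x docs matrix.

    Terms occurring in fewer than ``min_df`` documents are dropped and the
    document frequencies are recomputed afterwards.  Vocabulary order is
    lexicographic.  ``binary`` clips counts to 0/1 (MeSH-source matrices).
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    doc_ids = list(tokenized_docs.keys())
    # first pass: document frequency per term
    df: dict[str, int] = {}
    for toks in tokenized_docs.values():
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    terms = sorted(t for t, d in df.items() if d >= min_df)
    if not terms:
        logger.warning("all tokens filtered out; empty-vocabulary matrix")
    tindex = {t: i for i, t in enumerate(terms)}
    rows, cols, vals = [], [], []
    for j, did in enumerate(doc_ids):
        counts: dict[int, int] = {}
        for t in tokenized_docs[did]:
            i = tindex.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(1 if binary else c)
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(terms), len(doc_ids)), dtype=np.int64
    )
    doc_freq = np.asarray((counts_mat > 0).sum(axis=1)).ravel().astype(np.int64)
    return TermDocumentMatrix(Vocabulary(terms, doc_freq), doc_ids, counts_mat)


def reduce_vocabulary_for_topics(
    tdm: TermDocumentMatrix,
    extra_stoplist: frozenset[str] | set[str] | None = None,
    min_corpus_count: int = 50,
) -> tuple[TermDocumentMatrix, float]:
    """Prune the vocabulary ahead of topic modeling.

    Removes terms on ``extra_stoplist`` and terms whose corpus-wide count is
    below ``min_corpus_count``.  All documents are retained (rows may become
    empty).  Returns the reduced matrix and the retained-token fraction
    (new total count / old total count).
    """
    if min_corpus_count < 1:
        raise ValueError("min_corpus_count must be >= 1")
    if extra_stoplist is None:
        extra_stoplist = research_stopwords()
    corpus_counts = np.asarray(tdm.counts.sum(axis=1)).ravel()
    keep = np.array(
        [
            corpus_counts[i] >= min_corpus_count and t not in extra_stoplist
            for i, t in enumerate(tdm.vocabulary.terms)
        ],
        dtype=bool,
    )
    new_counts = sp.csr_matrix(tdm.counts[keep, :])
    new_terms = [t for t, k in zip(tdm.vocabulary.terms, keep) if k]
    doc_freq = np.asarray((new_counts > 0).sum(axis=1)).ravel().astype(np.int64)
    old_total = tdm.total_count
    reduced = TermDocumentMatrix(Vocabulary(new_terms, doc_freq), list(tdm.doc_ids), new_counts)
    fraction = reduced.total_count / old_total if old_total else 0.0
    return reduced, fraction


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_records_jsonl(path: str | Path) -> list[DocumentRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(DocumentRecord.from_json(json.loads(line)))
    return records


def write_records_jsonl(records: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json(), ensure_ascii=False) + "\n")


def write_matrix(tdm: TermDocumentMatrix, prefix: str | Path) -> None:
    """Write MTX + sidecar term/doc-id lists (order = matrix index)."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(tdm.counts))
    prefix.with_suffix(".terms.txt").write_text(
        "\n".join(tdm.vocabulary.terms) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join(tdm.doc_ids) + "\n", encoding="utf-8"
    )


def read_matrix(prefix: str | Path) -> TermDocumentMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    terms = prefix.with_suffix(".terms.txt").read_text(encoding="utf-8").splitlines()
    doc_ids = prefix.with_suffix(".docs.txt").read_text(encoding="utf-8").splitlines()
    counts = counts.astype(np.int64)
    doc_freq = np.asarray((counts > 0).sum(axis=1)).ravel().astype(np.int64)
    return TermDocumentMatrix(Vocabulary(terms, doc_freq), doc_ids, counts)
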