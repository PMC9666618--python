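"""Tidy tokenization and document-term matrix construction.

Abstracts (or full texts) are unnested into a one-token-per-row table,
cleaned of stopwords, search keywords and boilerplate tags, and counted into
a sparse document x term matrix.  The representation is deliberately
unstemmed single words: downstream dictionary scoring relies on wildcard
stems matched against surface forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus_io import BibRecord
from .term_analysis import match_pattern

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "DocTermMatrix",
    "default_stopwords",
    "tokenize",
    "tokenize_texts",
    "remove_stopwords",
    "remove_custom_terms",
    "build_dtm",
]

#: TokenTable = pandas DataFrame with columns ["doc_id", "token"], one row
#: per token occurrence, in document order.
TOKEN_COLUMNS = ["doc_id", "token"]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered term list with a dense 0-based term -> index map."""

    terms: tuple[str, ...]
    frequencies: np.ndarray  # corpus frequency per term, aligned with terms

    def __post_init__(self):
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.terms)})
        if len(self._index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    def __len__(self) -> int:
        return len(self.terms)

    def index(self, term: str) -> int:
        return self._index[term]

    def __contains__(self, term: str) -> bool:
        return term in self._index


@dataclass(frozen=True)
class DocTermMatrix:
    """Sparse D x V count matrix with row (document) and column (term) maps."""

    matrix: sp.csr_matrix
    doc_ids: tuple[str, ...]
    vocab: Vocabulary

    @property
    def n_docs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]

    @property
    def total_count(self) -> int:
        return int(self.matrix.sum())

    def to_mtx(self, path: str | Path) -> None:
        """Write the counts as MatrixMarket triplet text, with sidecar
        ``<path>.docs`` / ``<path>.terms`` label files."""
        from scipy.io import mmwrite

        path = Path(path)
        mmwrite(str(path), self.matrix.tocoo())
        path.with_suffix(path.suffix + ".docs").write_text(
            "\n".join(self.doc_ids) + "\n"
        )
        path.with_suffix(path.suffix + ".terms").write_text(
            "\n".join(self.vocab.terms) + "\n"
        )


def default_stopwords() -> frozenset[str]:
    """The shipped standard English stoplist (Snowball-style)."""
    text = resources.files("topictrends.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(w for w in text.split() if w)


def _tokenize_text(text: str) -> list[str]:
    """Case-fold, split on non-alphanumeric characters, drop standalone
    numerals and tokens shorter than 2 characters."""
    out: list[str] = []
    word: list[str] = []
    for ch in text.lower() + " ":
        if ch.isalnum():
            word.append(ch)
        elif word:
            tok = "".join(word)
            word.clear()
            if len(tok) >= 2 and not tok.isdigit():
                out.append(tok)
    return out


def tokenize_texts(texts: dict[str, str]) -> pd.DataFrame:
    """Tokenize a ``doc_id -> text`` mapping into a TokenTable."""
    doc_ids: list[str] = []
    tokens: list[str] = []
    for doc_id, text in texts.items():
        toks = _tokenize_text(text)
        doc_ids.extend([doc_id] * len(toks))
        tokens.extend(toks)
    return pd.DataFrame({"doc_id": doc_ids, "token": tokens})


def tokenize(records: Sequence[BibRecord], field: str = "abstract") -> pd.DataFrame:
    """Unnest a record text field into a one-token-per-row table.

    Records whose chosen field is absent are skipped with a warning.
    """
    texts: dict[str, str] = {}
    for r in records:
        value = getattr(r, field)
        if value is None:
            logger.warning("record %s has no %s; skipped", r.record_id, field)
            continue
        texts[r.record_id] = value
    return tokenize_texts(texts)


def remove_stopwords(tokens: pd.DataFrame, stoplist: Iterable[str] | None = None) -> pd.DataFrame:
    """Drop rows whose token is in the stoplist (default: shipped English list)."""
    stoplist = frozenset(stoplist) if stoplist is not None else default_stopwords()
    if not stoplist:
        raise ValueError("stoplist must be non-empty")
    keep = ~tokens["token"].isin(stoplist)
    out = tokens[keep].reset_index(drop=True)
    logger.info("stopword removal: %d of %d rows dropped", len(tokens) - len(out), len(tokens))
    return out


def remove_custom_terms(tokens: pd.DataFrame, patterns: Sequence[str]) -> pd.DataFrame:
    """Drop rows matching any wildcard pattern (trailing ``*`` = prefix).

    Used to strip search keywords and publisher boilerplate tags.  Removal
    counts per pattern are logged.
    """
    if not patterns:
        return tokens.copy()
    unique = pd.unique(tokens["token"])
    matched_terms: set[str] = set()
    for pat in patterns:
        hits = {t for t in unique if match_pattern(pat, t)}
        n_rows = int(tokens["token"].isin(hits).sum())
        logger.info("pattern %r removed %d token rows", pat, n_rows)
        matched_terms |= hits
    keep = ~tokens["token"].isin(matched_terms)
    return tokens[keep].reset_index(drop=True)


def build_dtm(tokens: pd.DataFrame, min_term_freq: int = 1) -> DocTermMatrix:
    """Count a TokenTable into a sparse document-term matrix.

    Terms with corpus frequency below ``min_term_freq`` are excluded from the
    vocabulary; documents left without tokens are dropped with a logged
    list.  Raises if no document survives.
    """
    if len(tokens) == 0:
        raise ValueError("cannot build a document-term matrix from an empty token table")
    freq = tokens["token"].value_counts()
    kept_terms = freq[freq >= min_term_freq]
    if kept_terms.empty:
        raise ValueError(f"no term reaches min_term_freq={min_term_freq}")
    surviving = tokens[tokens["token"].isin(kept_terms.index)]

    all_docs = list(dict.fromkeys(tokens["doc_id"]))  # first-appearance order
    kept_docs = set(surviving["doc_id"])
    dropped = [d for d in all_docs if d not in kept_docs]
    if dropped:
        logger.warning("%d documents dropped as empty after pruning: %s", len(dropped), dropped)
    if not kept_docs:
        raise ValueError("all documents empty after term pruning")
    doc_ids = tuple(d for d in all_docs if d in kept_docs)
    terms = tuple(sorted(kept_terms.index))
    doc_index = {d: i for i, d in enumerate(doc_ids)}
    term_index = {t: i for i, t in enumerate(terms)}

    rows = surviving["doc_id"].map(doc_index).to_numpy()
    cols = surviving["token"].map(term_index).to_numpy()
    matrix = sp.coo_matrix(
        (np.ones(len(surviving), dtype=np.int64), (rows, cols)),
        shape=(len(doc_ids), len(terms)),
    ).tocsr()
    matrix.sum_duplicates()
    frequencies = np.asarray(matrix.sum(axis=0)).ravel()
    return DocTermMatrix(matrix=matrix, doc_ids=doc_ids, vocab=Vocabulary(terms, frequencies))
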