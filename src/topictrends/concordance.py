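"""Abstract vs full-text assignment concordance (bias check).

Abstract-only topic modelling is far cheaper than full-text modelling, but
may misrepresent documents.  The check implemented here takes the m
best-fitting documents of every topic (highest gamma under the abstract
model), refits a topic model of the same k on their full texts, aligns the
two topic labellings by optimal assignment on the agreement contingency
table, and reports the percentage of documents assigned to matched topics.
The agreement percentage is invariant to any permutation of either model's
topic labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .lda import LdaConfig, LdaModel, fit_lda_config
from .preprocess import build_dtm, remove_custom_terms, remove_stopwords, tokenize_texts
from .trends import assign_topics

logger = logging.getLogger(__name__)

__all__ = ["ConcordanceResult", "select_top_fitting", "match_topics", "concordance_check"]


@dataclass
class ConcordanceResult:
    """Outcome of the concordance check.

    ``pct_agree`` is the raw percentage 100 * n_agree / n_available;
    ``pct_agree_rounded`` is its nearest-integer report form.
    """

    n_requested: int
    n_available: int
    n_agree: int
    pct_agree: float
    topic_mapping: dict[int, int]
    table: pd.DataFrame  # doc_id, abstract_topic, fulltext_topic_mapped, agree

    @property
    def pct_agree_rounded(self) -> int:
        return int(round(self.pct_agree))


def select_top_fitting(assignment: pd.DataFrame, m: int = 20) -> dict[int, list[str]]:
    """The m highest-gamma documents of every topic.

    Topics holding fewer than m documents contribute what they have (logged).
    Gamma ties keep the original table order.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    out: dict[int, list[str]] = {}
    for t, sub in assignment.groupby("topic"):
        ranked = sub.sort_values("max_gamma", ascending=False, kind="stable")
        ids = ranked["doc_id"].head(m).tolist()
        if len(ids) < m:
            logger.info("topic %s has only %d documents (< m=%d)", t, len(ids), m)
        out[int(t)] = ids
    return out


def match_topics(
    assign_a: pd.DataFrame, assign_b: pd.DataFrame, docs: list[str] | None = None
) -> dict[int, int]:
    """Best bijective topic mapping between two assignments.

    Builds the topic x topic contingency table over the shared documents and
    solves the optimal assignment maximizing total agreement (Hungarian
    algorithm), mapping the first model's topics onto the second's.  With
    unequal topic counts the mapping covers min(k_a, k_b) topics.
    """
    a = assign_a.set_index("doc_id")["topic"]
    b = assign_b.set_index("doc_id")["topic"]
    if docs is None:
        docs = [d for d in a.index if d in set(b.index)]
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    table = np.zeros((ka, kb), dtype=np.int64)
    for d in docs:
        table[a[d], b[d]] += 1
    rows, cols = linear_sum_assignment(-table)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def agreement(
    assign_a: pd.DataFrame, assign_b: pd.DataFrame, docs: list[str] | None = None
) -> tuple[int, dict[int, int], pd.DataFrame]:
    """Per-document agreement under the optimal topic mapping."""
    mapping = match_topics(assign_a, assign_b, docs)
    a = assign_a.set_index("doc_id")["topic"]
    b = assign_b.set_index("doc_id")["topic"]
    if docs is None:
        docs = [d for d in a.index if d in set(b.index)]
    rows = []
    n_agree = 0
    for d in docs:
        mapped = mapping.get(int(a[d]), -1)
        ok = mapped == int(b[d])
        n_agree += ok
        rows.append(
            {"doc_id": d, "abstract_topic": int(a[d]),
             "fulltext_topic_mapped": mapped, "fulltext_topic": int(b[d]), "agree": bool(ok)}
        )
    return n_agree, mapping, pd.DataFrame(rows)


def concordance_check(
    abstract_model: LdaModel,
    fulltexts: dict[str, str],
    m: int = 20,
    stoplist=None,
    custom_patterns: tuple[str, ...] = (),
    min_term_freq: int = 1,
    lda_config: LdaConfig | None = None,
    seed: int = 0,
) -> ConcordanceResult:
    """Run the full bias check.

    ``fulltexts`` maps doc_id to plain text; missing full texts are
    tolerated and reduce ``n_available``.  The full-text refit uses the same
    cleaning configuration and the same k as the abstract model.
    """
    lda_config = lda_config or LdaConfig()
    abstract_assignment = assign_topics(abstract_model)
    per_topic = select_top_fitting(abstract_assignment, m=m)
    requested = [d for ids in per_topic.values() for d in ids]
    available = [d for d in requested if d in fulltexts]
    missing = len(requested) - len(available)
    if missing:
        logger.info("%d of %d requested full texts unavailable", missing, len(requested))
    if len(available) < 2:
        raise ValueError(f"need at least 2 available full texts, got {len(available)}")

    tokens = tokenize_texts({d: fulltexts[d] for d in available})
    tokens = remove_stopwords(tokens, stoplist)
    tokens = remove_custom_terms(tokens, custom_patterns)
    dtm = build_dtm(tokens, min_term_freq=min_term_freq)
    fulltext_model = fit_lda_config(dtm, abstract_model.k, lda_config, seed=seed)
    fulltext_assignment = assign_topics(fulltext_model)

    shared = [d for d in available if d in set(fulltext_assignment["doc_id"])]
    n_agree, mapping, table = agreement(
        abstract_assignment[abstract_assignment["doc_id"].isin(shared)],
        fulltext_assignment,
        docs=shared,
    )
    return ConcordanceResult(
        n_requested=len(requested),
        n_available=len(shared),
        n_agree=n_agree,
        pct_agree=100.0 * n_agree / len(shared),
        topic_mapping=mapping,
        table=table,
    )
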