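"""Topic-term ranking and dictionary-based term-group scoring.

A *term group* is a named set of wildcard patterns (trailing ``*`` means
prefix match, anything else is an exact, case-folded match) describing a
thematic field, e.g. ``Agriculture = {agricult*, crop*, farm*, yield*}``.
A group's score within a topic is the sum of 100*beta over the terms of that
topic's top-N word list (N = 100 by default) matching at least one pattern,
each term counted once per group even under multiple pattern hits.  Summing
the per-topic scores gives the group's grand total, a simple quantitative
summary of how strongly a thematic field is represented across topics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .lda import LdaModel

__all__ = [
    "TermGroup",
    "match_pattern",
    "top_terms",
    "score_term_groups",
    "default_term_groups",
    "load_term_groups",
]


@dataclass(frozen=True)
class TermGroup:
    """A named, case-folded wildcard pattern set."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError(f"term group {self.name!r} has no patterns")
        object.__setattr__(self, "patterns", tuple(p.casefold() for p in self.patterns))

    def matches(self, term: str) -> bool:
        return any(match_pattern(p, term) for p in self.patterns)


def match_pattern(pattern: str, term: str) -> bool:
    """True iff ``term`` matches the wildcard ``pattern``.

    A trailing ``*`` makes the pattern a prefix stem ("agricult*" matches
    "agriculture" and "agricultural"); otherwise the match is exact.
    Comparison is case-folded.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pattern = pattern.casefold()
    term = term.casefold()
    if pattern.endswith("*"):
        return term.startswith(pattern[:-1])
    return term == pattern


def top_terms(model: "LdaModel", topic: int, n: int = 100) -> list[tuple[str, float]]:
    """The ``n`` highest-beta terms of a topic, ties broken lexicographically."""
    beta_row = model.beta[topic]
    if not 1 <= n <= beta_row.shape[0]:
        raise ValueError(f"n must be in [1, {beta_row.shape[0]}], got {n}")
    terms = np.asarray(model.terms)
    # sort by (-beta, term): lexsort's last key is primary
    order = np.lexsort((terms, -beta_row))[:n]
    return [(str(terms[i]), float(beta_row[i])) for i in order]


def default_term_groups() -> list[TermGroup]:
    """The shipped thematic dictionary (economic sectors, policy, economics,
    nature conservation, taxonomic categories, CICES ecosystem-service
    categories).  Editable: load your own with :func:`load_term_groups`."""
    text = resources.files("topictrends.data").joinpath("term_groups.json").read_text()
    return [TermGroup(name, tuple(pats)) for name, pats in json.loads(text).items()]


def load_term_groups(path: str | Path) -> list[TermGroup]:
    """Load a ``{group name: [patterns...]}`` JSON dictionary file."""
    data = json.loads(Path(path).read_text())
    return [TermGroup(name, tuple(pats)) for name, pats in data.items()]


def score_term_groups(
    model: "LdaModel",
    groups: Sequence[TermGroup] | None = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """Score each term group within each topic's top-``top_n`` word list.

    Returns a tidy frame with one row per (group, topic): ``sum_beta_pct``
    (sum of 100*beta over matched terms) and ``matched_terms``.  A grand
    per-group total appears as extra rows with ``topic = -1``.  Scores are
    additive: per-topic rows of a group sum to its total row.
    """
    if groups is None:
        groups = default_term_groups()
    top_n = min(top_n, len(model.terms))
    rows = []
    for g in groups:
        total = 0.0
        per_topic_rows = []
        for k in range(model.k):
            ranked = top_terms(model, k, n=top_n)
            matched = [(t, b) for t, b in ranked if g.matches(t)]
            score = 100.0 * sum(b for _, b in matched)
            total += score
            per_topic_rows.append(
                {
                    "group": g.name,
                    "topic": k,
                    "sum_beta_pct": score,
                    "matched_terms": [t for t, _ in matched],
                }
            )
        rows.extend(per_topic_rows)
        rows.append(
            {"group": g.name, "topic": -1, "sum_beta_pct": total, "matched_terms": []}
        )
    return pd.DataFrame(rows, columns=["group", "topic", "sum_beta_pct", "matched_terms"])


def score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy scores into a report table: one row per group, the grand
    total and one ``topic_k`` column per topic, beta% rounded to 3 decimals."""
    per_topic = scores[scores["topic"] >= 0].pivot(
        index="group", columns="topic", values="sum_beta_pct"
    )
    per_topic.columns = [f"topic_{k}" for k in per_topic.columns]
    totals = scores[scores["topic"] == -1].set_index("group")["sum_beta_pct"]
    out = pd.concat([totals.rename("sum_beta_pct"), per_topic], axis=1)
    return out.round(3)
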