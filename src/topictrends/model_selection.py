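"""Topic-number selection by the gamma-exclusivity rule.

The working number of topics is chosen by fitting the model over a grid of
candidate k values and keeping the largest k at which documents still belong
*nearly exclusively* to a single topic — their highest gamma exceeds a
threshold close to 1 (default 0.999).  Two readings of "documents belong
nearly exclusively" are implemented:

* ``any_document`` (default): at least one document exceeds the threshold;
* ``per_topic``: every topic owns at least one such document.

If no k on the grid qualifies, the smallest grid value is returned with a
warning.  The exclusivity diagnostics are pure functions of the fitted
gamma matrices, so they can be evaluated on externally supplied models
without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lda import LdaConfig, LdaModel, fit_lda_config
from .preprocess import DocTermMatrix

logger = logging.getLogger(__name__)

__all__ = ["KSelectionResult", "exclusivity_diagnostics", "choose_k", "select_k"]


@dataclass
class KSelectionResult:
    """Grid diagnostics and the chosen topic count."""

    k_grid: tuple[int, ...]
    diagnostics: pd.DataFrame  # one row per k
    chosen_k: int
    threshold: float
    rule: str
    models: dict[int, LdaModel] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.diagnostics.to_csv(path, index=False)


def exclusivity_diagnostics(
    gammas: Mapping[int, np.ndarray], threshold: float
) -> pd.DataFrame:
    """Per-k exclusivity summary computed from gamma matrices alone.

    Columns: ``k``, ``max_gamma`` (max over documents of the row maximum),
    ``n_exclusive_docs`` (documents with row max > threshold) and
    ``n_topics_with_exclusive`` (topics holding the argmax of at least one
    such document).
    """
    rows = []
    for k in sorted(gammas):
        g = np.asarray(gammas[k])
        row_max = g.max(axis=1)
        exclusive = row_max > threshold
        winners = g.argmax(axis=1)[exclusive]
        rows.append(
            {
                "k": k,
                "max_gamma": float(row_max.max()) if g.size else float("nan"),
                "n_exclusive_docs": int(exclusive.sum()),
                "n_topics_with_exclusive": int(np.unique(winners).size),
            }
        )
    return pd.DataFrame(rows, columns=["k", "max_gamma", "n_exclusive_docs", "n_topics_with_exclusive"])


def choose_k(
    diagnostics: pd.DataFrame, k_grid: Sequence[int], threshold: float, rule: str
) -> int:
    """Apply the selection rule to a diagnostics table."""
    if rule not in ("any_document", "per_topic"):
        raise ValueError(f"unknown rule {rule!r}")
    qualifying = []
    for row in diagnostics.itertuples():
        if rule == "any_document":
            ok = row.n_exclusive_docs >= 1
        else:
            ok = row.n_topics_with_exclusive == row.k
        if ok:
            qualifying.append(int(row.k))
    if qualifying:
        return max(qualifying)
    logger.warning(
        "no k in grid %s reaches exclusivity threshold %g; falling back to min(k_grid)",
        list(k_grid), threshold,
    )
    return min(k_grid)


def select_k(
    dtm: DocTermMatrix,
    k_grid: Sequence[int] = (5, 9, 10, 20, 30),
    threshold: float = 0.999,
    rule: str = "any_document",
    config: LdaConfig | None = None,
    base_seed: int = 0,
    keep_models: bool = True,
) -> KSelectionResult:
    """Fit the model over ``k_grid`` and choose the working topic count.

    One fit per k, seeded deterministically with ``base_seed + k``.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if any(k < 2 for k in k_grid):
        raise ValueError("all k in the grid must be >= 2")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    config = config or LdaConfig()
    models: dict[int, LdaModel] = {}
    for k in sorted(set(k_grid)):
        logger.info("fitting k=%d", k)
        models[k] = fit_lda_config(dtm, k, config, seed=base_seed + k)
    diagnostics = exclusivity_diagnostics({k: m.gamma for k, m in models.items()}, threshold)
    chosen = choose_k(diagnostics, list(k_grid), threshold, rule)
    return KSelectionResult(
        k_grid=tuple(k_grid),
        diagnostics=diagnostics,
        chosen_k=chosen,
        threshold=threshold,
        rule=rule,
        models=models if keep_models else {},
    )
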