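"""Topic assignment, per-topic summary metrics and annual trend regressions.

Every document is assigned to the topic with its highest gamma value.  From
that partition the module derives the reporting tables used to compare
topics: per-topic totals (article count, mean gamma with standard error,
mean citations with standard error, beta% range of the ten top words),
per-topic annual series, and ordinary-least-squares trend fits with the
slope F-test.  Four regression families are computed per topic:

* annual article count vs year;
* annual mean gamma vs year;
* annual citation sum vs year;
* annual mean citations vs annual article count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus_io import BibRecord
from .lda import LdaModel
from .term_analysis import top_terms

logger = logging.getLogger(__name__)

__all__ = [
    "TrendFit",
    "assign_topics",
    "topic_summary",
    "annual_series",
    "fit_trend",
    "trend_table",
]

REGRESSION_FAMILIES = (
    "articles_vs_year",
    "mean_gamma_vs_year",
    "citations_vs_year",
    "citations_vs_articles",
)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of y on x with intercept; F-test of the slope on (1, n-2) df."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n_points: int
    alpha: float
    significant: bool


def assign_topics(model: LdaModel) -> pd.DataFrame:
    """Assign each document to its argmax-gamma topic.

    Returns a frame with columns ``doc_id``, ``topic``, ``max_gamma``.
    Gamma ties are broken by the lowest topic index (logged).
    """
    topics = model.gamma.argmax(axis=1)
    max_gamma = model.gamma.max(axis=1)
    n_ties = int(((model.gamma == max_gamma[:, None]).sum(axis=1) > 1).sum())
    if n_ties:
        logger.warning("%d documents had tied gamma maxima; lowest topic index kept", n_ties)
    return pd.DataFrame(
        {"doc_id": list(model.doc_ids), "topic": topics, "max_gamma": max_gamma}
    )


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean: sample SD / sqrt(n); NaN for n < 2."""
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def topic_summary(
    assignment: pd.DataFrame,
    records: Sequence[BibRecord],
    model: LdaModel,
    top_n_beta: int = 10,
) -> pd.DataFrame:
    """Per-topic reporting table after argmax assignment.

    One row per topic: ``n_articles``, ``mean_gamma``/``se_gamma`` over the
    assigned documents' max gamma, ``mean_citations``/``se_citations``, and
    the (min, max) of beta% over the topic's ``top_n_beta`` highest-beta
    terms.  Topics with no assigned article report NaN metrics, not zeros.
    """
    citations = {r.record_id: r.citations for r in records}
    merged = assignment.assign(
        citations=assignment["doc_id"].map(citations)
    )
    rows = []
    for k in range(model.k):
        sub = merged[merged["topic"] == k]
        ranked = top_terms(model, k, n=min(top_n_beta, len(model.terms)))
        betas = [b for _, b in ranked]
        row = {
            "topic": k,
            "n_articles": int(len(sub)),
            "mean_gamma": float(sub["max_gamma"].mean()) if len(sub) else float("nan"),
            "se_gamma": _sem(sub["max_gamma"].to_numpy()) if len(sub) else float("nan"),
            "mean_citations": float(sub["citations"].mean()) if len(sub) else float("nan"),
            "se_citations": _sem(sub["citations"].to_numpy(dtype=float)) if len(sub) else float("nan"),
            "beta_pct_min_top": 100.0 * min(betas),
            "beta_pct_max_top": 100.0 * max(betas),
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    assert int(out["n_articles"].sum()) == len(assignment)
    return out


def annual_series(
    assignment: pd.DataFrame,
    records: Sequence[BibRecord],
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-(topic, year) metrics over a contiguous year grid.

    Columns: ``n_articles``, ``mean_gamma``, ``se_gamma``, ``sum_citations``,
    ``mean_citations``.  Years with no article appear with ``n_articles=0``
    and NaN means so that trend fits can drop or keep them explicitly.
    """
    meta = {r.record_id: (r.year, r.citations) for r in records}
    years = assignment["doc_id"].map(lambda d: meta[d][0])
    if years.isna().any():
        raise ValueError("every assigned record needs a valid year")
    frame = assignment.assign(
        year=years.astype(int),
        citations=assignment["doc_id"].map(lambda d: meta[d][1]),
    )
    if year_range is None:
        year_range = (int(frame["year"].min()), int(frame["year"].max()))
    all_years = range(year_range[0], year_range[1] + 1)
    topics = sorted(frame["topic"].unique())
    rows = []
    grouped = frame.groupby(["topic", "year"])
    for t in topics:
        for y in all_years:
            try:
                sub = grouped.get_group((t, y))
            except KeyError:
                sub = frame.iloc[0:0]
            rows.append(
                {
                    "topic": t,
                    "year": y,
                    "n_articles": int(len(sub)),
                    "mean_gamma": float(sub["max_gamma"].mean()) if len(sub) else float("nan"),
                    "se_gamma": _sem(sub["max_gamma"].to_numpy()) if len(sub) else float("nan"),
                    "sum_citations": int(sub["citations"].sum()),
                    "mean_citations": float(sub["citations"].mean()) if len(sub) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def fit_trend(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> TrendFit:
    """OLS of y on x with intercept; F-test of the slope (1, n-2 df).

    Pairs with a missing value on either side are dropped; at least three
    complete pairs and non-constant x are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete (x, y) pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p = float(model.f_pvalue)
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=p,
        n_points=int(len(x)),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def trend_table(annual: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit the four regression families for every topic.

    Returns one row per (topic, family) with the :class:`TrendFit` fields;
    families that cannot be fitted (too few complete points) appear with NaN
    statistics.
    """
    rows = []
    for t, sub in annual.groupby("topic"):
        families = {
            "articles_vs_year": (sub["year"], sub["n_articles"]),
            "mean_gamma_vs_year": (sub["year"], sub["mean_gamma"]),
            "citations_vs_year": (sub["year"], sub["sum_citations"]),
            "citations_vs_articles": (sub["n_articles"], sub["mean_citations"]),
        }
        for fam, (x, y) in families.items():
            base = {"topic": t, "family": fam}
            try:
                fit = fit_trend(x, y, alpha=alpha)
                base.update(
                    slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared,
                    f_statistic=fit.f_statistic, p_value=fit.p_value,
                    n_points=fit.n_points, significant=fit.significant,
                )
            except ValueError:
                base.update(
                    slope=np.nan, intercept=np.nan, r_squared=np.nan,
                    f_statistic=np.nan, p_value=np.nan, n_points=0, significant=False,
                )
            rows.append(base)
    return pd.DataFrame(rows)
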