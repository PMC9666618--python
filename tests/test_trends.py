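import numpy as np
import pandas as pd
import pytest
import scipy.stats

import topictrends as tt
from topictrends.lda import LdaModel


def _model_from_gamma(gamma, beta=None, doc_ids=None):
    gamma = np.asarray(gamma, dtype=float)
    d, k = gamma.shape
    if beta is None:
        beta = np.full((k, 10), 0.1)
    beta = np.asarray(beta, dtype=float)
    return LdaModel(
        k=k, alpha=0.1, eta=0.1, beta=beta, gamma=gamma, seed=0, sweeps=1,
        burn_in=0, trace=np.zeros(1),
        doc_ids=tuple(doc_ids) if doc_ids else tuple(f"d{i}" for i in range(d)),
        terms=tuple(f"t{i}" for i in range(beta.shape[1])),
    )


def _ols_closed_form(x, y):
    """Normal-equations oracle for slope/intercept/R2/F."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    r2 = 1 - ss_res / ss_tot
    f = (ss_tot - ss_res) / (ss_res / (n - 2))
    p = scipy.stats.f.sf(f, 1, n - 2)
    return slope, intercept, r2, f, p


class TestAssignTopics:
    def test_argmax_row(self):
        m = _model_from_gamma([[0.7, 0.2, 0.1]])
        out = tt.assign_topics(m)
        assert out.loc[0, "topic"] == 0
        assert out.loc[0, "max_gamma"] == pytest.approx(0.7)

    def test_tie_goes_to_lowest_index(self):
        out = tt.assign_topics(_model_from_gamma([[0.5, 0.5]]))
        assert out.loc[0, "topic"] == 0

    def test_matches_row_scan_oracle(self, rng):
        gamma = rng.dirichlet(np.ones(6), size=500)
        out = tt.assign_topics(_model_from_gamma(gamma))
        for d in range(500):
            best, arg = -1.0, -1
            for j in range(6):
                if gamma[d, j] > best:
                    best, arg = gamma[d, j], j
            assert out.loc[d, "topic"] == arg
            assert out.loc[d, "max_gamma"] == pytest.approx(best)

    def test_partition_sums_to_d(self, block_model):
        out = tt.assign_topics(block_model)
        assert len(out) == block_model.gamma.shape[0]
        assert out["topic"].between(0, block_model.k - 1).all()


class TestTopicSummary:
    def test_hand_arithmetic(self):
        gamma = [[0.6, 0.4], [0.8, 0.2], [0.1, 0.9]]
        model = _model_from_gamma(gamma)
        records = [
            tt.BibRecord("d0", "T", "a", 2010, 10),
            tt.BibRecord("d1", "T", "a", 2011, 30),
            tt.BibRecord("d2", "T", "a", 2012, 5),
        ]
        summary = tt.topic_summary(tt.assign_topics(model), records, model)
        row = summary[summary["topic"] == 0].iloc[0]
        assert row["n_articles"] == 2
        assert row["mean_gamma"] == pytest.approx(0.7)
        assert row["se_gamma"] == pytest.approx(0.1)  # sd 0.1414 / sqrt(2)
        assert row["mean_citations"] == pytest.approx(20.0)

    def test_flat_top10_beta_range(self):
        beta = np.full((2, 20), 0.006)
        beta[:, 10:] = (1 - 0.006 * 10) / 10
        # make the first 10 the top by bumping them above the rest
        beta = np.full((2, 20), 0.004)
        beta[:, :10] = 0.006
        beta /= beta.sum(axis=1, keepdims=True)
        # renormalisation keeps the flat structure; compare min == max
        model = _model_from_gamma([[1.0, 0.0]], beta=beta)
        summary = tt.topic_summary(tt.assign_topics(model), [tt.BibRecord("d0", "T", "a", 2010, 0)], model)
        assert summary.loc[0, "beta_pct_min_top"] == pytest.approx(summary.loc[0, "beta_pct_max_top"])

    def test_empty_topic_reports_nan_not_zero(self):
        model = _model_from_gamma([[0.9, 0.1]])
        summary = tt.topic_summary(
            tt.assign_topics(model), [tt.BibRecord("d0", "T", "a", 2010, 3)], model
        )
        row = summary[summary["topic"] == 1].iloc[0]
        assert row["n_articles"] == 0
        assert np.isnan(row["mean_gamma"]) and np.isnan(row["mean_citations"])

    def test_planted_citation_means_recovered(self):
        means = (5.0, 40.0, 90.0)
        corpus = tt.generate_corpus(
            tt.SyntheticCorpusSpec(
                n_topics=3, vocab_size=60, n_docs=600, doc_length=30.0,
                citation_means=means, seed=5,
            )
        )
        assignment = pd.DataFrame(
            {
                "doc_id": list(corpus.dtm.doc_ids),
                "topic": corpus.labels_true,
                "max_gamma": 1.0,
            }
        )
        model = _model_from_gamma(np.eye(3)[corpus.labels_true], doc_ids=corpus.dtm.doc_ids)
        summary = tt.topic_summary(assignment, corpus.records, model)
        for k, mu in enumerate(means):
            row = summary[summary["topic"] == k].iloc[0]
            assert abs(row["mean_citations"] - mu) <= 2 * row["se_citations"] + 1e-9


class TestAnnualSeries:
    def test_grouping_counts(self):
        model = _model_from_gamma([[1, 0], [1, 0], [1, 0]])
        records = [
            tt.BibRecord("d0", "T", "a", 2005, 1),
            tt.BibRecord("d1", "T", "a", 2005, 2),
            tt.BibRecord("d2", "T", "a", 2006, 3),
        ]
        annual = tt.annual_series(tt.assign_topics(model), records)
        t0 = annual[annual["topic"] == 0].set_index("year")
        assert t0.loc[2005, "n_articles"] == 2
        assert t0.loc[2006, "n_articles"] == 1
        assert t0.loc[2005, "sum_citations"] == 3

    def test_conservation_against_topic_summary(self, block_corpus, block_model):
        assignment = tt.assign_topics(block_model)
        summary = tt.topic_summary(assignment, block_corpus.records, block_model)
        annual = tt.annual_series(assignment, block_corpus.records)
        per_topic = annual.groupby("topic")["n_articles"].sum()
        for _, row in summary.iterrows():
            if row["n_articles"]:
                assert per_topic[row["topic"]] == row["n_articles"]

    def test_zero_years_present_with_nan_means(self):
        model = _model_from_gamma([[1, 0]])
        records = [tt.BibRecord("d0", "T", "a", 2005, 1)]
        annual = tt.annual_series(tt.assign_topics(model), records, year_range=(2004, 2006))
        t0 = annual[annual["topic"] == 0].set_index("year")
        assert t0.loc[2004, "n_articles"] == 0
        assert np.isnan(t0.loc[2004, "mean_gamma"])


class TestFitTrend:
    def test_perfect_line(self):
        x = np.arange(5.0)
        fit = tt.fit_trend(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10
        assert fit.significant

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n) * 10
            y = 1.5 * x + rng.normal(size=n)
            fit = tt.fit_trend(x, y)
            slope, intercept, r2, f, p = _ols_closed_form(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-8)
            assert fit.intercept == pytest.approx(intercept, abs=1e-8)
            assert fit.r_squared == pytest.approx(r2, abs=1e-8)
            assert fit.f_statistic == pytest.approx(f, rel=1e-8)
            assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_textbook_style_fixture(self):
        # classic hand-checked regression: x = study hours, y = scores
        x = [1, 2, 3, 4, 5]
        y = [2, 4, 5, 4, 5]
        fit = tt.fit_trend(x, y)
        assert fit.slope == pytest.approx(0.6)
        assert fit.intercept == pytest.approx(2.2)
        assert fit.r_squared == pytest.approx(0.6)

    def test_nan_pairs_dropped(self):
        x = [1, 2, 3, 4, np.nan]
        y = [2, 4, np.nan, 8, 10]
        fit = tt.fit_trend(x, y)
        assert fit.n_points == 3
        assert fit.slope == pytest.approx(2.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            tt.fit_trend([1, 2], [1, 2])
        with pytest.raises(ValueError):
            tt.fit_trend([3, 3, 3, 3], [1, 2, 3, 4])

    def test_growth_slope_recovered_from_generator(self):
        corpus = tt.generate_corpus(
            tt.SyntheticCorpusSpec(
                n_topics=3, vocab_size=60, n_docs=2200, doc_length=10.0,
                growth=(2.0, 0.0, 0.0), seed=17,
            )
        )
        years = np.array([r.year for r in corpus.records])
        labels = corpus.labels_true
        ys = np.arange(2000, 2021)
        counts = [(labels[years == y] == 0).sum() for y in ys]
        fit = tt.fit_trend(ys, counts)
        # Poisson noise around a slope-2 intensity: accept a generous CI
        se = np.sqrt(np.mean(counts)) / np.sqrt(np.sum((ys - ys.mean()) ** 2))
        assert abs(fit.slope - 2.0) < 4 * se + 0.3


class TestTrendTable:
    def test_four_families_per_topic(self, block_corpus, block_model):
        assignment = tt.assign_topics(block_model)
        annual = tt.annual_series(assignment, block_corpus.records)
        table = tt.trend_table(annual)
        families = set(table["family"])
        assert families == {
            "articles_vs_year", "mean_gamma_vs_year",
            "citations_vs_year", "citations_vs_articles",
        }
        assert (table.groupby("topic").size() == 4).all()
        ok = table.dropna(subset=["p_value"])
        assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()
        assert (ok["significant"] == (ok["p_value"] < 0.05)).all()
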