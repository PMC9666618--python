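import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topictrends as tt
from topictrends.lda import LdaModel
from topictrends.term_analysis import score_table


def _model(beta, terms):
    beta = np.asarray(beta, dtype=float)
    k, v = beta.shape
    return LdaModel(
        k=k, alpha=0.1, eta=0.1, beta=beta,
        gamma=np.full((1, k), 1.0 / k), seed=0, sweeps=1, burn_in=0,
        trace=np.zeros(1), doc_ids=("d0",), terms=tuple(terms),
    )


class TestTopTerms:
    def test_ranked_prefix(self):
        m = _model([[0.5, 0.3, 0.2]], ["a", "b", "c"])
        assert tt.top_terms(m, 0, n=2) == [("a", 0.5), ("b", 0.3)]

    def test_tie_broken_lexicographically(self):
        m = _model([[0.4, 0.2, 0.4]], ["b", "c", "a"])
        assert tt.top_terms(m, 0, n=1) == [("a", 0.4)]

    def test_matches_full_sort_oracle(self, rng):
        v = 300
        beta = rng.dirichlet(np.ones(v))
        terms = [f"t{i:03d}" for i in range(v)]
        m = _model(beta[None, :], terms)
        got = tt.top_terms(m, 0, n=100)
        expected = sorted(zip(terms, beta), key=lambda p: (-p[1], p[0]))[:100]
        assert [t for t, _ in got] == [t for t, _ in expected]

    def test_n_bounds(self):
        m = _model([[0.5, 0.5]], ["a", "b"])
        with pytest.raises(ValueError):
            tt.top_terms(m, 0, n=0)
        with pytest.raises(ValueError):
            tt.top_terms(m, 0, n=3)


class TestMatchPattern:
    @pytest.mark.parametrize(
        "pattern,term,expected",
        [
            ("agricult*", "agriculture", True),
            ("agricult*", "agricultural", True),
            ("agricult*", "aquaculture", False),
            ("fish", "fishery", False),
            ("fish", "fish", True),
            ("Fish", "FISH", True),  # case-folded
            ("water*", "water", True),
        ],
    )
    def test_cases(self, pattern, term, expected):
        assert tt.match_pattern(pattern, term) is expected

    @given(st.text("abcde", min_size=1, max_size=6), st.text("abcde", max_size=8))
    @settings(derandomize=True, max_examples=200)
    def test_prefix_oracle(self, stem, term):
        assert tt.match_pattern(stem + "*", term) == term.startswith(stem)
        assert tt.match_pattern(stem, term) == (term == stem)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            tt.match_pattern("", "x")


def _random_dictionary_model(rng, k=9):
    """Random beta over a vocabulary mixing shipped-dictionary surface forms
    and neutral filler terms."""
    dictionary_terms = [
        "agriculture", "crops", "farming", "yield", "timber", "forest",
        "fish", "water", "policy", "sustainable", "conservation", "nature",
        "bird", "microbial", "climate", "soil", "biomass", "market",
    ]
    filler = [f"term{i:03d}" for i in range(60)]
    terms = dictionary_terms + filler
    beta = rng.dirichlet(np.ones(len(terms)), size=k)
    return _model(beta, terms)


class TestScoreTermGroups:
    def test_hand_arithmetic(self):
        m = _model([[0.05, 0.02, 0.01]], ["policy", "crop", "yield"])
        g = tt.TermGroup("Agriculture", ("crop*", "yield*"))
        scores = tt.score_term_groups(m, [g], top_n=3)
        row = scores[(scores["group"] == "Agriculture") & (scores["topic"] == 0)].iloc[0]
        assert row["sum_beta_pct"] == pytest.approx(3.0)
        assert sorted(row["matched_terms"]) == ["crop", "yield"]

    def test_term_matching_two_patterns_counted_once(self):
        m = _model([[0.6, 0.4]], ["farming", "other"])
        g = tt.TermGroup("Agriculture", ("farm*", "farming"))
        scores = tt.score_term_groups(m, [g], top_n=2)
        assert scores.iloc[0]["sum_beta_pct"] == pytest.approx(60.0)

    def test_empty_match_scores_zero(self):
        m = _model([[1.0]], ["unrelated"])
        scores = tt.score_term_groups(m, [tt.TermGroup("X", ("zzz",))], top_n=1)
        assert scores.iloc[0]["sum_beta_pct"] == 0.0
        assert scores.iloc[0]["matched_terms"] == []

    def test_matches_triple_loop_oracle_with_shipped_dictionary(self, rng):
        groups = tt.default_term_groups()
        m = _random_dictionary_model(rng)
        top_n = 40
        scores = tt.score_term_groups(m, groups, top_n=top_n)
        for g in groups:
            for k in range(m.k):
                ranked = tt.top_terms(m, k, n=top_n)
                expected = 0.0
                for term, beta in ranked:
                    if any(tt.match_pattern(p, term) for p in g.patterns):
                        expected += 100.0 * beta
                row = scores[(scores["group"] == g.name) & (scores["topic"] == k)].iloc[0]
                assert row["sum_beta_pct"] == pytest.approx(expected, abs=1e-12)

    def test_additivity_and_monotonicity_on_random_models(self, rng):
        groups = tt.default_term_groups()
        for _ in range(100):
            m = _random_dictionary_model(rng, k=3)
            scores = tt.score_term_groups(m, groups, top_n=30)
            smaller = tt.score_term_groups(m, groups, top_n=10)
            for g in groups:
                sub = scores[scores["group"] == g.name]
                total = sub[sub["topic"] == -1]["sum_beta_pct"].iloc[0]
                assert total == pytest.approx(
                    sub[sub["topic"] >= 0]["sum_beta_pct"].sum(), abs=1e-9
                )
                assert total <= 100.0 * m.k + 1e-9
                for k in range(m.k):
                    big = sub[sub["topic"] == k]["sum_beta_pct"].iloc[0]
                    small = smaller[
                        (smaller["group"] == g.name) & (smaller["topic"] == k)
                    ]["sum_beta_pct"].iloc[0]
                    assert small <= big + 1e-12

    def test_score_bounded_by_100(self, rng):
        m = _random_dictionary_model(rng)
        scores = tt.score_term_groups(m, top_n=78)
        per_topic = scores[scores["topic"] >= 0]
        assert (per_topic["sum_beta_pct"] <= 100.0 + 1e-9).all()

    def test_score_table_shape(self, rng):
        m = _random_dictionary_model(rng, k=3)
        table = score_table(tt.score_term_groups(m, top_n=20))
        assert list(table.columns) == ["sum_beta_pct", "topic_0", "topic_1", "topic_2"]
        assert len(table) == len(tt.default_term_groups())


class TestDictionaryIO:
    def test_load_round_trip(self, tmp_path):
        path = tmp_path / "groups.json"
        path.write_text('{"G": ["a*", "b"]}')
        (g,) = tt.load_term_groups(path)
        assert g.name == "G" and g.patterns == ("a*", "b")

    def test_default_groups_present(self):
        names = {g.name for g in tt.default_term_groups()}
        assert {"Agriculture", "Forestry", "Fishery", "Policy", "Economics",
                "Nature conservation", "Taxonomic categories",
                "CICES ES categories"} <= names

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            tt.TermGroup("X", ())
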