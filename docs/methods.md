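# Methods

## Scope and data model

The package analyses a bibliographic corpus: records with a unique id, title,
abstract, publication year, citation count, document type and language, read from
tab-delimited export files (default column labels follow the Web-of-Science-style
two-letter tags UT/TI/AB/PY/TC/DT/LA; the dialect is fully configurable, since
export conventions vary by database and vintage). Deduplication keeps the first
occurrence, keyed by record id when present and otherwise by case-folded,
whitespace-normalised title — ids are authoritative when available. Screening
filters (abstract required, year window, document types, languages) are applied in
a fixed declared order and each removed record is attributed to the first filter it
fails, so the removal report always balances: input = retained + Σ removed.
Records whose year cannot be parsed are removed by the year filter with a warning.

## Preprocessing

Abstracts (or full texts) are unnested into a one-token-per-row table: text is
case-folded and split on non-alphanumeric characters; standalone numerals and
tokens shorter than two characters are dropped. No stemming or lemmatisation is
applied — the dictionary scoring stage matches wildcard stems (`agricult*`)
against surface forms, which presumes unstemmed terms. A standard Snowball-style
English stoplist ships as package data (editable/replaceable); search keywords and
publisher boilerplate are removed with the same wildcard pattern syntax used
everywhere in the package: a trailing `*` means prefix match, anything else is an
exact case-folded match. Note that a stem is a string prefix — `service*` matches
*service* and *services* but not *servicing*, whose seventh letter differs. The
document–term matrix holds raw counts; terms below a corpus-frequency floor
(default 1, i.e. no pruning) are dropped, and documents emptied by pruning are
dropped with a logged list.

## Topic model and inference

LDA with symmetric Dirichlet priors: document–topic concentration α (default
50/k, a common heuristic), topic–word concentration η (default 0.1). Inference is
collapsed Gibbs sampling; the sampler state is the token-level assignment vector
and its count tables, updated by the standard collapsed conditional. The kernel is
compiled with numba and seeds numba's Mersenne state once per chain, so a fit is
bit-reproducible given (matrix, k, α, η, sweeps, seed) on a given platform.
Defaults: 1000 sweeps, 500 burn-in.

Two estimators of β and γ are provided. `"mean"` (default) averages the count
tables over post-burn-in sweeps before smoothing — lower variance, the right
choice for reporting and trend work. `"final"` smooths the last state only; it is
used by the topic-number selection stage because sweep-averaging blurs exactly the
near-degenerate γ values (γ → 1) that the exclusivity rule looks for. The
per-sweep trace records the collapsed joint log p(w, z) (up to constants), used
for convergence inspection and for choosing among restarts: the collapsed
posterior is multimodal (a classic failure mode merges two planted topics and
splits a third), so `fit_lda(..., restarts=r)` runs r independently seeded chains
and keeps the best final trace value, still deterministic in the seed.

Topic labels are arbitrary; wherever an estimate is compared with planted truth or
a second model, topics are aligned by the Hungarian algorithm (on β-row cosines,
or on the agreement contingency table) — never inside the sampler.

## Choosing the number of topics

The selection rule fits a grid of k (default {5, 9, 10, 20, 30}) and keeps the
largest k at which documents still belong *nearly exclusively* to one topic:
max γ > threshold, default 0.999. Because the wording "articles belonged nearly
exclusively" is genuinely ambiguous, both readings are implemented:
`any_document` (default; one such document suffices) and `per_topic` (every topic
must own one). If no k qualifies, the smallest grid value is returned with a
warning. One fit per k uses seed = base_seed + k.

The rule has a sharp, analysable sensitivity. For a document of length N whose
tokens all sit in one topic, the smoothed γ maximum is (N+α)/(N+kα), which
exceeds 0.999 iff N > 1000·α·(0.999k − 1). With α = 0.012 that bound is ≈96
tokens at k = 9 but ≈108 at k = 10: on a corpus with Poisson(75) document lengths
the longest documents clear the first bound and not the second, so the rule
separates adjacent k values purely through the prior mass — this is why the
planted-9-topic validation uses a small fixed α rather than 50/k (under which γ
can never approach 1 at these document lengths), and the final-state estimator.
Because the decision rides on the corpus's longest few documents, a small
fraction of generator seeds fall outside the analytic window; the validation
suite pins a verified seed.

## Trend statistics

Every document goes to its argmax-γ topic (ties to the lowest index, logged). The
per-topic summary reports n, mean and SE of the assigned documents' max γ, mean
and SE of citations, and the β%-range (min, max of 100·β) over the topic's ten
top terms. SE is the sample standard deviation divided by √n. Empty topics report
absent (NaN) metrics, never zeros. Annual series are integer year bins over a
contiguous range; empty years appear with n = 0 and absent means. Four OLS
regression families are fitted per topic — article count, mean γ and citation sum
against year, and mean citations against article count — each with an intercept
and the slope F-test on (1, n−2) df, via statsmodels; pairs with missing values
are dropped and at least three complete pairs with non-constant x are required.
Citation counts are static as-of-retrieval values; no citation-ageing correction
is applied.

## Term-group scoring

A term group is a named wildcard pattern set; its score in a topic is the sum of
100·β over the terms of that topic's top-N list (default N = 100) matching at
least one pattern, with each term counted once per group even when several
patterns hit it (avoiding double counting). Per-topic scores are additive to the
group's grand total, every score is bounded by 100 per topic, and shrinking N can
only shrink a score. A default dictionary of eight thematic groups (agriculture,
forestry, fishery, policy, economics, nature conservation, taxonomic categories,
CICES ecosystem-service categories) ships as editable JSON; it includes a few
multi-word entries that single-token matching can never hit — kept deliberately,
as the single-word representation is a known limitation of this kind of scoring.

## Concordance check

To gauge whether abstract-only modelling biases assignment, the m (default 20)
highest-γ documents of each topic are selected, a model with the same k and
cleaning configuration is refitted on their full texts only, the two labellings
are aligned by optimal assignment on the agreement contingency table, and the
percentage of documents in matched topics is reported (raw and nearest-integer).
Missing full texts are tolerated and reduce the denominator. Agreement is
invariant to permuting either model's labels, and identical inputs with identical
seeds reproduce 100%.

## Synthetic corpora

The generator emulates the structure such a corpus is expected to have, with full
ground truth. Topic–word rows are Dirichlet draws — or, with `separation` on,
supported on K disjoint vocabulary blocks, the well-separated regime used for
recovery validation. Per-(topic, year) article counts are Poisson around linear
annual intensities whose slope is the configured growth (articles/year), so
`n_docs` is the expected total; the generator refuses growth values that would
drive intensities negative. Document lengths are Poisson; tokens are multinomial
draws from the document's mixture (in mixture mode θ is an exact draw from the
symmetric Dirichlet conditioned on its argmax being the planted label, obtained
by exchangeability). Citations are Poisson with per-topic means, or negative
binomial when overdispersion is wanted. Synthetic vocabularies are neutral
(`term0001`, ...) with optional injection of dictionary-matching surface forms
into chosen topics so term scoring is exercised meaningfully. Full texts are
abstracts padded with extra tokens drawn from the planted topic with a set
consistency. Everything is determined by the seed.

What the generator does **not** emulate: natural-language syntax, realistic word
frequency (Zipf) profiles, topic correlation, citation networks or citation
ageing. Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not performance on real abstracts.

## Validation sizes and numerical choices

Validation runs are deliberately small — e.g. recovery on D≈500, V=200, K=5 with
60-token documents; the selection-rule check on D≈450, V=270, K=9 with 75-token
documents and 400 sweeps; reference-implementation comparison on D≈130, V≈51,
K=3 — sizes at which the planted structure is comfortably identifiable while a
full grid of fits completes in seconds. Held-out perplexity comparisons against
an external fit use a shared deterministic per-document EM fold-in for θ, so both
topic–word matrices are scored identically. Probabilities are floored at 1e-300
before logs; simplex sums are asserted to 1e-8. The trend F-test's calibration is
checked empirically (type-I error ≈ 5% on 1000 null series).

## Known limitations

Single-word tokens only (no phrases/n-grams); no hyperparameter optimisation of
α/η; no coherence-based model selection (the exclusivity rule is the primary
criterion by design); exact numerical reproduction of any particular published
corpus analysis is out of scope — the corpus-specific topics, counts and scores
depend on the underlying database export, which such papers typically do not
deposit.
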