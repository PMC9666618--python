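"""Synthetic bibliographic corpora drawn from the LDA generative process.

Real bibliographic corpora are rarely redistributable, so every pipeline
stage is exercised against corpora generated here with known ground truth:
Dirichlet topic-word distributions (optionally block-structured so each
topic owns a disjoint vocabulary slice), Dirichlet document-topic weights,
multinomial token draws, publication years with per-topic linear growth in
expected annual article count, and per-topic Poisson (or negative binomial)
citation counts.  Generation is fully determined by the seed, and the
planted parameters are returned alongside the records so estimators can be
validated against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus_io import BibRecord
from .preprocess import DocTermMatrix, Vocabulary

__all__ = ["SyntheticCorpusSpec", "SyntheticCorpus", "generate_corpus", "generate_fulltexts"]


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of a synthetic corpus.

    ``n_docs`` is the expected total document count: the realised per-
    (topic, year) counts are Poisson draws around a linear annual intensity
    with per-topic slope ``growth`` (articles/year, 0 by default), subject
    to the constraint that intensities stay non-negative over the year
    range.  ``doc_length`` is the Poisson mean token count per document.
    With ``separation`` on, the vocabulary is split into K equal disjoint
    blocks and each document draws all its tokens from its own topic's
    block — the well-separated regime used for truth-recovery checks.
    Otherwise documents are full LDA mixtures with weights
    ``theta ~ Dirichlet(alpha_true)`` and the planted label is argmax theta.
    """

    n_topics: int = 9
    vocab_size: int = 270
    n_docs: int = 450
    doc_length: float = 75.0
    alpha_true: float = 0.1
    eta_true: float = 0.1
    separation: bool = True
    year_range: tuple[int, int] = (2000, 2020)
    growth: tuple[float, ...] | float = 0.0
    citation_means: tuple[float, ...] | float = 25.0
    citation_dispersion: float | None = None  # neg. binomial size; None = Poisson
    inject_terms: dict[int, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_topics, self.vocab_size, self.n_docs) < 1 or self.doc_length <= 0:
            raise ValueError("counts must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("invalid year_range")

    def growth_per_topic(self) -> np.ndarray:
        g = self.growth
        if np.isscalar(g):
            return np.full(self.n_topics, float(g))
        g = np.asarray(g, dtype=float)
        if g.shape != (self.n_topics,):
            raise ValueError("growth must be scalar or length n_topics")
        return g

    def citations_per_topic(self) -> np.ndarray:
        c = self.citation_means
        if np.isscalar(c):
            return np.full(self.n_topics, float(c))
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_topics,):
            raise ValueError("citation_means must be scalar or length n_topics")
        return c


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its planted truth."""

    records: list[BibRecord]
    dtm: DocTermMatrix
    beta_true: np.ndarray  # (K, V)
    theta_true: np.ndarray  # (D, K)
    labels_true: np.ndarray  # (D,) planted topic per document
    token_lists: dict[str, list[int]]  # doc_id -> drawn term indices, in order
    spec: SyntheticCorpusSpec

    def truth_json(self, path: str | Path) -> None:
        payload = {
            "n_topics": self.spec.n_topics,
            "vocab_size": self.spec.vocab_size,
            "seed": self.spec.seed,
            "labels_true": self.labels_true.tolist(),
            "beta_true": self.beta_true.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _make_vocab(spec: SyntheticCorpusSpec) -> list[str]:
    width = len(str(spec.vocab_size))
    terms = [f"term{i:0{width}d}" for i in range(spec.vocab_size)]
    block = spec.vocab_size // spec.n_topics
    for topic, names in spec.inject_terms.items():
        start = topic * block if spec.separation else 0
        for j, name in enumerate(names):
            terms[start + j] = name
    return terms


def _planted_beta(spec: SyntheticCorpusSpec, rng: np.random.Generator) -> np.ndarray:
    K, V = spec.n_topics, spec.vocab_size
    if spec.separation:
        block = V // K
        beta = np.zeros((K, V))
        for k in range(K):
            lo = k * block
            hi = V if k == K - 1 else lo + block
            weights = rng.dirichlet(np.full(hi - lo, max(spec.eta_true, 1e-3) * 10))
            beta[k, lo:hi] = weights
        return beta
    return rng.dirichlet(np.full(V, spec.eta_true), size=K)


def _doc_counts_by_year(spec: SyntheticCorpusSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson (topic, year) article counts around linear annual intensities."""
    y0, y1 = spec.year_range
    n_years = y1 - y0 + 1
    growth = spec.growth_per_topic()
    mean_per_cell = spec.n_docs / (spec.n_topics * n_years)
    intensities = np.empty((spec.n_topics, n_years))
    for k in range(spec.n_topics):
        base = mean_per_cell - growth[k] * (n_years - 1) / 2.0
        if base < 0:
            raise ValueError(
                f"growth {growth[k]}/yr needs a mean annual count of at least "
                f"{growth[k] * (n_years - 1) / 2:.1f} per topic; increase n_docs"
            )
        intensities[k] = base + growth[k] * np.arange(n_years)
    return rng.poisson(intensities)


def generate_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Draw a corpus (records + document-term matrix + planted truth)."""
    rng = np.random.default_rng(spec.seed)
    terms = _make_vocab(spec)
    beta = _planted_beta(spec, rng)
    counts_ty = _doc_counts_by_year(spec, rng)
    K = spec.n_topics
    y0, _ = spec.year_range
    citation_means = spec.citations_per_topic()

    labels: list[int] = []
    years: list[int] = []
    for k in range(K):
        for yi, c in enumerate(counts_ty[k]):
            labels.extend([k] * int(c))
            years.extend([y0 + yi] * int(c))
    order = rng.permutation(len(labels))
    labels_arr = np.asarray(labels)[order]
    years_arr = np.asarray(years)[order]
    D = len(labels_arr)

    theta = np.zeros((D, K))
    records: list[BibRecord] = []
    token_lists: dict[str, list[int]] = {}
    rows, cols, vals = [], [], []
    width = len(str(D))
    for d in range(D):
        k_d = int(labels_arr[d])
        if spec.separation:
            theta[d, k_d] = 1.0
            word_probs = beta[k_d]
        else:
            th = rng.dirichlet(np.full(K, spec.alpha_true))
            # symmetric Dirichlet is exchangeable: swapping the largest
            # component into the planted slot yields an exact draw from the
            # Dirichlet conditioned on argmax theta == planted label
            j = int(th.argmax())
            th[j], th[k_d] = th[k_d], th[j]
            theta[d] = th
            word_probs = th @ beta
        n_tokens = max(1, int(rng.poisson(spec.doc_length)))
        drawn = rng.choice(spec.vocab_size, size=n_tokens, p=word_probs)
        doc_id = f"SYN{d:0{width}d}"
        token_lists[doc_id] = drawn.tolist()
        uniq, cnt = np.unique(drawn, return_counts=True)
        rows.extend([d] * len(uniq))
        cols.extend(uniq.tolist())
        vals.extend(cnt.tolist())
        if spec.citation_dispersion is None:
            cites = int(rng.poisson(citation_means[k_d]))
        else:
            size = spec.citation_dispersion
            p = size / (size + citation_means[k_d])
            cites = int(rng.negative_binomial(size, p))
        records.append(
            BibRecord(
                record_id=doc_id,
                title=f"Synthetic document {d}",
                abstract=" ".join(terms[w] for w in drawn),
                year=int(years_arr[d]),
                citations=cites,
                doc_type="article",
                language="english",
            )
        )

    matrix = sp.coo_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(D, spec.vocab_size)
    ).tocsr()
    vocab = Vocabulary(tuple(terms), np.asarray(matrix.sum(axis=0)).ravel())
    dtm = DocTermMatrix(matrix=matrix, doc_ids=tuple(r.record_id for r in records), vocab=vocab)
    return SyntheticCorpus(
        records=records, dtm=dtm, beta_true=beta, theta_true=theta,
        labels_true=labels_arr, token_lists=token_lists, spec=spec,
    )


def generate_fulltexts(
    corpus: SyntheticCorpus,
    expansion_factor: float = 2.0,
    consistency: float = 1.0,
    seed: int | None = None,
) -> dict[str, str]:
    """Synthesize full texts as topic-padded abstracts.

    Each full text is the abstract's token sequence plus
    ``(expansion_factor - 1) * len(abstract)`` extra tokens, drawn from the
    document's planted topic with probability ``consistency`` and from a
    uniformly random other topic otherwise.
    """
    if expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    if not 0.0 <= consistency <= 1.0:
        raise ValueError("consistency must be in [0, 1]")
    spec = corpus.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    terms = corpus.dtm.vocab.terms
    out: dict[str, str] = {}
    for d, doc_id in enumerate(corpus.dtm.doc_ids):
        base = corpus.token_lists[doc_id]
        n_extra = int(round((expansion_factor - 1.0) * len(base)))
        extra: list[int] = []
        k_true = int(corpus.labels_true[d])
        for _ in range(n_extra):
            if rng.random() < consistency:
                k = k_true
            else:
                k = int(rng.integers(spec.n_topics - 1))
                if k >= k_true:
                    k += 1
            extra.append(int(rng.choice(spec.vocab_size, p=corpus.beta_true[k])))
        out[doc_id] = " ".join(terms[w] for w in list(base) + extra)
    return out


def write_fulltexts(fulltexts: dict[str, str], outdir: str | Path) -> None:
    """Write one ``<doc_id>.txt`` per document (the concordance input layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc_id, text in fulltexts.items():
        (outdir / f"{doc_id}.txt").write_text(text)


def read_fulltexts(indir: str | Path) -> dict[str, str]:
    """Read a directory of ``<doc_id>.txt`` plain-text files."""
    return {p.stem: p.read_text() for p in sorted(Path(indir).glob("*.txt"))}
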