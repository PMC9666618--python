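"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

LDA models each document as a mixture over k latent topics and each topic as
a distribution over vocabulary terms.  Fitting yields two simplex matrices:

* ``beta``  (k x V): probability of each term given a topic;
* ``gamma`` (D x k): probability of each topic given a document
  ("prevalence") — the quantity used downstream to assign every document to
  its best-fitting topic.

Inference is collapsed Gibbs sampling over token-level topic assignments
with symmetric Dirichlet priors (document-topic concentration ``alpha``,
topic-word concentration ``eta``).  The reported beta and gamma are, by
default, posterior means of the smoothed count tables over post-burn-in
sweeps; ``estimator="final"`` uses the last state instead, which preserves
the near-degenerate gamma values that exclusivity-based topic-number
selection looks for.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gibbs import run_gibbs
from .preprocess import DocTermMatrix

logger = logging.getLogger(__name__)

__all__ = ["LdaModel", "LdaConfig", "fit_lda", "log_likelihood", "held_out_perplexity"]


@dataclass(frozen=True)
class LdaModel:
    """A fitted topic model.

    ``beta`` rows and ``gamma`` rows are probability simplexes (sum to 1).
    ``trace`` holds one collapsed joint log-likelihood value per sweep.
    """

    k: int
    alpha: float
    eta: float
    beta: np.ndarray  # (k, V)
    gamma: np.ndarray  # (D, k)
    seed: int
    sweeps: int
    burn_in: int
    trace: np.ndarray  # (sweeps,)
    doc_ids: tuple[str, ...]
    terms: tuple[str, ...]

    @property
    def beta_pct(self) -> np.ndarray:
        """beta x 100, the percentage form used in reporting tables."""
        return self.beta * 100.0

    @property
    def gamma_pct(self) -> np.ndarray:
        return self.gamma * 100.0

    def save(self, outdir: str | Path) -> None:
        """Serialize to a directory: beta/gamma as labelled CSV, metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.beta, columns=list(self.terms)).to_csv(outdir / "beta.csv", index_label="topic")
        pd.DataFrame(self.gamma, index=list(self.doc_ids)).to_csv(outdir / "gamma.csv", index_label="doc_id")
        meta = {
            "k": self.k,
            "alpha": self.alpha,
            "eta": self.eta,
            "seed": self.seed,
            "sweeps": self.sweeps,
            "burn_in": self.burn_in,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
        np.savetxt(outdir / "trace.txt", self.trace)

    @classmethod
    def load(cls, indir: str | Path) -> "LdaModel":
        indir = Path(indir)
        meta = json.loads((indir / "metadata.json").read_text())
        beta_df = pd.read_csv(indir / "beta.csv", index_col="topic")
        gamma_df = pd.read_csv(indir / "gamma.csv", index_col="doc_id")
        return cls(
            beta=beta_df.to_numpy(),
            gamma=gamma_df.to_numpy(),
            trace=np.loadtxt(indir / "trace.txt"),
            doc_ids=tuple(str(d) for d in gamma_df.index),
            terms=tuple(beta_df.columns),
            **meta,
        )


@dataclass(frozen=True)
class LdaConfig:
    """Sampler hyperparameters.  ``alpha=None`` uses the 50/k heuristic."""

    alpha: float | None = None
    eta: float = 0.1
    sweeps: int = 1000
    burn_in: int = 500
    estimator: str = "mean"  # "mean" (post-burn-in average) or "final"

    def resolved_alpha(self, k: int) -> float:
        return 50.0 / k if self.alpha is None else self.alpha


def _tokens_from_dtm(dtm: DocTermMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expand the count matrix into aligned (doc, word) token arrays in
    deterministic row-major order."""
    coo = dtm.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    counts = coo.data[order]
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("document-term matrix must hold integer counts")
        counts = np.round(counts).astype(np.int64)
    doc_ids = np.repeat(coo.row[order].astype(np.int64), counts)
    word_ids = np.repeat(coo.col[order].astype(np.int64), counts)
    return doc_ids, word_ids


def fit_lda(
    dtm: DocTermMatrix,
    k: int,
    alpha: float | None = None,
    eta: float = 0.1,
    sweeps: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    estimator: str = "mean",
    restarts: int = 1,
) -> LdaModel:
    """Fit a k-topic model to a document-term matrix.

    Parameters follow the usual symmetric-prior parameterization; ``alpha``
    defaults to 50/k.  ``sweeps`` > ``burn_in`` >= 0 is required; the
    posterior mean uses the ``sweeps - burn_in`` retained states.  Identical
    inputs and seed give bit-identical beta and gamma.

    The collapsed posterior is multimodal (e.g. two merged topics plus one
    split topic is a local mode); ``restarts`` > 1 runs that many
    independently seeded chains and keeps the one with the highest final
    joint log-likelihood, still deterministically in ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not sweeps > burn_in >= 0:
        raise ValueError(f"need sweeps > burn_in >= 0, got {sweeps}, {burn_in}")
    if dtm.total_count == 0:
        raise ValueError("empty document-term matrix")
    if k > dtm.n_docs:
        warnings.warn(f"k={k} exceeds the number of documents ({dtm.n_docs})")
    if estimator not in ("mean", "final"):
        raise ValueError(f"unknown estimator {estimator!r}")
    alpha_val = 50.0 / k if alpha is None else float(alpha)
    if alpha_val <= 0 or eta <= 0:
        raise ValueError("alpha and eta must be positive")

    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    doc_ids, word_ids = _tokens_from_dtm(dtm)
    best = None
    for r in range(restarts):
        chain = run_gibbs(
            doc_ids, word_ids, dtm.n_docs, dtm.n_terms, k,
            alpha_val, float(eta), int(sweeps), int(burn_in),
            (int(seed) + 1000003 * r) & 0x7FFFFFFF,
        )
        if best is None or chain[5][-1] > best[5][-1]:
            best = chain
    z, n_dk_mean, n_kw_mean, n_dk_final, n_kw_final, trace = best
    if estimator == "mean":
        n_dk, n_kw = n_dk_mean, n_kw_mean
    else:
        n_dk, n_kw = n_dk_final.astype(np.float64), n_kw_final.astype(np.float64)

    beta = (n_kw + eta) / (n_kw.sum(axis=1, keepdims=True) + dtm.n_terms * eta)
    gamma = (n_dk + alpha_val) / (n_dk.sum(axis=1, keepdims=True) + k * alpha_val)
    return LdaModel(
        k=k, alpha=alpha_val, eta=float(eta),
        beta=beta, gamma=gamma,
        seed=int(seed), sweeps=int(sweeps), burn_in=int(burn_in), trace=trace,
        doc_ids=tuple(dtm.doc_ids), terms=tuple(dtm.vocab.terms),
    )


def fit_lda_config(dtm: DocTermMatrix, k: int, config: LdaConfig, seed: int) -> LdaModel:
    """Convenience wrapper taking an :class:`LdaConfig`."""
    return fit_lda(
        dtm, k,
        alpha=config.alpha, eta=config.eta,
        sweeps=config.sweeps, burn_in=config.burn_in,
        seed=seed, estimator=config.estimator,
    )


def log_likelihood(model: LdaModel, dtm: DocTermMatrix) -> float:
    """Mixture log-likelihood sum_d sum_w n_dw log sum_j gamma_dj beta_jw."""
    if model.beta.shape[1] != dtm.n_terms or model.gamma.shape[0] != dtm.n_docs:
        raise ValueError("model dimensions do not match the document-term matrix")
    coo = dtm.matrix.tocoo()
    probs = np.einsum("ij,ji->i", model.gamma[coo.row], model.beta[:, coo.col])
    return float(np.sum(coo.data * np.log(probs)))


def fold_in_gamma(
    beta: np.ndarray, dtm: DocTermMatrix, alpha: float = 0.1, n_iter: int = 100
) -> np.ndarray:
    """Estimate document-topic weights for a fixed beta by per-document EM.

    Deterministic (uniform initialization), so it provides a common footing
    for comparing topic-word matrices from different inference back ends.
    """
    K = beta.shape[0]
    X = dtm.matrix.tocsr()
    gamma = np.full((dtm.n_docs, K), 1.0 / K)
    logs = []
    for d in range(dtm.n_docs):
        start, end = X.indptr[d], X.indptr[d + 1]
        words = X.indices[start:end]
        counts = X.data[start:end].astype(np.float64)
        b = beta[:, words]  # (K, nw)
        theta = np.full(K, 1.0 / K)
        for _ in range(n_iter):
            phi = b * theta[:, None]  # (K, nw)
            phi /= np.maximum(phi.sum(axis=0, keepdims=True), 1e-300)
            theta = phi @ counts + alpha
            theta /= theta.sum()
        gamma[d] = theta
        logs.append(float(counts @ np.log(np.maximum(theta @ b, 1e-300))))
    return gamma


def held_out_perplexity(
    beta: np.ndarray, dtm: DocTermMatrix, alpha: float = 0.1, n_iter: int = 100
) -> float:
    """Held-out perplexity exp(-log p / N) of a topic-word matrix on unseen
    documents, with document weights folded in by :func:`fold_in_gamma`."""
    gamma = fold_in_gamma(beta, dtm, alpha=alpha, n_iter=n_iter)
    coo = dtm.matrix.tocoo()
    probs = np.einsum("ij,ji->i", gamma[coo.row], beta[:, coo.col])
    ll = float(np.sum(coo.data * np.log(np.maximum(probs, 1e-300))))
    return float(np.exp(-ll / dtm.total_count))
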