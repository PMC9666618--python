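"""Truth-recovery evaluation helpers for label-switched topic models.

Topic labels are arbitrary in any mixture model; before an estimated model
can be compared with planted truth the topics must be aligned.  Alignment
here uses the Hungarian algorithm on the topic x topic cosine-similarity
matrix of beta rows.  These helpers live outside the sampler on purpose:
inference never sees the truth.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_beta", "matched_beta_cosines", "assignment_accuracy"]


def _row_normalise(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    return m / np.maximum(norms, 1e-300)


def match_beta(beta_est: np.ndarray, beta_true: np.ndarray) -> np.ndarray:
    """Permutation mapping estimated topic j to true topic perm[j],
    maximizing the summed beta-row cosine similarity."""
    sim = _row_normalise(beta_est) @ _row_normalise(beta_true).T
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(beta_est.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm


def matched_beta_cosines(beta_est: np.ndarray, beta_true: np.ndarray) -> np.ndarray:
    """Per-topic cosine similarity after optimal matching."""
    perm = match_beta(beta_est, beta_true)
    a = _row_normalise(beta_est)
    b = _row_normalise(beta_true)
    return np.array([float(a[j] @ b[perm[j]]) for j in range(beta_est.shape[0])])


def assignment_accuracy(
    labels_est: np.ndarray, labels_true: np.ndarray, perm: np.ndarray
) -> float:
    """Fraction of documents whose matched estimated topic equals the
    planted topic."""
    mapped = perm[np.asarray(labels_est)]
    return float(np.mean(mapped == np.asarray(labels_true)))
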