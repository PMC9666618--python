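"""Numba kernels for the collapsed Gibbs sampler.

The sampler state is the token-level topic assignment vector z plus three
count tables: n_dk (document x topic), n_kw (topic x term) and n_k (topic
totals).  One sweep resamples every token from the collapsed conditional

    p(z_i = j | z_-i, w) propto (n_dj + alpha) (n_jw + eta) / (n_j + V eta)

with the token's own count removed.  Post-burn-in count tables are
accumulated for the posterior-mean estimator.  All randomness comes from
numba's Mersenne state seeded once inside the kernel, so a run is
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _joint_log_likelihood(n_dk, n_kw, n_k, doc_len, alpha, eta):
    """Collapsed joint log p(w, z) up to additive constants in (alpha, eta)."""
    K, V = n_kw.shape
    D = n_dk.shape[0]
    ll = 0.0
    for k in range(K):
        for w in range(V):
            if n_kw[k, w] > 0:
                ll += math.lgamma(n_kw[k, w] + eta) - math.lgamma(eta)
        ll -= math.lgamma(n_k[k] + V * eta) - math.lgamma(V * eta)
    for d in range(D):
        for k in range(K):
            if n_dk[d, k] > 0:
                ll += math.lgamma(n_dk[d, k] + alpha) - math.lgamma(alpha)
        ll -= math.lgamma(doc_len[d] + K * alpha) - math.lgamma(K * alpha)
    return ll


@njit(cache=True)
def run_gibbs(doc_ids, word_ids, D, V, K, alpha, eta, sweeps, burn_in, seed):
    """Run the sampler; return (z, n_dk_mean, n_kw_mean, n_dk, n_kw, trace)."""
    np.random.seed(seed)
    N = doc_ids.shape[0]
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    doc_len = np.zeros(D, dtype=np.int64)
    z = np.empty(N, dtype=np.int64)
    for i in range(N):
        k0 = int(np.random.random() * K)
        if k0 == K:  # guard the measure-zero edge
            k0 = K - 1
        z[i] = k0
        n_dk[doc_ids[i], k0] += 1
        n_kw[k0, word_ids[i]] += 1
        n_k[k0] += 1
        doc_len[doc_ids[i]] += 1

    n_dk_sum = np.zeros((D, K), dtype=np.float64)
    n_kw_sum = np.zeros((K, V), dtype=np.float64)
    trace = np.empty(sweeps, dtype=np.float64)
    cum = np.empty(K, dtype=np.float64)
    Veta = V * eta

    for s in range(sweeps):
        for i in range(N):
            d = doc_ids[i]
            w = word_ids[i]
            k_old = z[i]
            n_dk[d, k_old] -= 1
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            total = 0.0
            for k in range(K):
                total += (n_dk[d, k] + alpha) * (n_kw[k, w] + eta) / (n_k[k] + Veta)
                cum[k] = total
            u = np.random.random() * total
            k_new = 0
            while cum[k_new] < u and k_new < K - 1:
                k_new += 1
            z[i] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
        trace[s] = _joint_log_likelihood(n_dk, n_kw, n_k, doc_len, alpha, eta)
        if s >= burn_in:
            n_dk_sum += n_dk
            n_kw_sum += n_kw

    n_saved = sweeps - burn_in
    return z, n_dk_sum / n_saved, n_kw_sum / n_saved, n_dk, n_kw, trace


@njit(cache=True)
def check_counts(n_dk, n_kw):
    """Debug invariant: both tables sum to the total token count."""
    return n_dk.sum() == n_kw.sum()
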