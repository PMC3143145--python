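"""Numba-jitted Gibbs sweep kernel for the admixture model.

Same model as the numpy reference path in :mod:`mitonuc.clustering` (which
remains available as ``engine='numpy'`` and serves as a consistency
cross-check): allele-copy assignments Z, cluster allele frequencies P with a
Dirichlet(lambda) prior, individual ancestry Q with a symmetric
Dirichlet(alpha) prior, and a random-walk Metropolis update of alpha under a
uniform prior on (0, alpha_max].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_admixture(
    ind_idx,      # (M,) int64 individual of each observed allele copy
    flat_la,      # (M,) int64 locus * Amax + allele code
    n, L, Amax, K,
    n_states,     # (L,) int64 valid states per locus
    Z0,           # (M,) int64 initial assignments
    burn_in, reps,
    lambda_prior, alpha_init, alpha_max, alpha_sd,
    no_admixture,  # 0/1
    seed,
):
    np.random.seed(seed)
    M = ind_idx.shape[0]
    LA = L * Amax
    Z = Z0.copy()
    alpha = alpha_init
    P = np.zeros((K, LA))
    Q = np.full((n, K), 1.0 / K)
    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, LA))
    alpha_sum = 0.0
    ll_sum = 0.0
    ll_sq = 0.0
    kept = 0
    counts = np.zeros((K, LA))
    qcounts = np.zeros((n, K))
    logp = np.zeros(K)

    for sweep in range(reps):
        # --- P | Z
        counts[:, :] = 0.0
        for m in range(M):
            counts[Z[m], flat_la[m]] += 1.0
        for k in range(K):
            for l in range(L):
                tot = 0.0
                for a in range(n_states[l]):
                    g = np.random.gamma(lambda_prior + counts[k, l * Amax + a], 1.0)
                    P[k, l * Amax + a] = g
                    tot += g
                for a in range(n_states[l]):
                    P[k, l * Amax + a] /= tot
        # --- Q | Z
        qcounts[:, :] = 0.0
        for m in range(M):
            qcounts[ind_idx[m], Z[m]] += 1.0
        if K == 1:
            Q[:, 0] = 1.0
        elif no_admixture == 0:
            for i in range(n):
                tot = 0.0
                for k in range(K):
                    g = np.random.gamma(alpha + qcounts[i, k], 1.0)
                    Q[i, k] = g
                    tot += g
                for k in range(K):
                    Q[i, k] /= tot
        else:
            # one origin per individual, sampled from its marginal likelihood
            for i in range(n):
                for k in range(K):
                    logp[k] = 0.0
            # accumulate per-individual log-likelihoods
            lp = np.zeros((n, K))
            for m in range(M):
                i = ind_idx[m]
                for k in range(K):
                    p = P[k, flat_la[m]]
                    lp[i, k] += math.log(p if p > 1e-300 else 1e-300)
            for i in range(n):
                mx = lp[i, 0]
                for k in range(1, K):
                    if lp[i, k] > mx:
                        mx = lp[i, k]
                tot = 0.0
                for k in range(K):
                    lp[i, k] = math.exp(lp[i, k] - mx)
                    tot += lp[i, k]
                u = np.random.random() * tot
                acc = 0.0
                pick = K - 1
                for k in range(K):
                    acc += lp[i, k]
                    if u <= acc:
                        pick = k
                        break
                for k in range(K):
                    Q[i, k] = 0.0
                Q[i, pick] = 1.0
        # --- Z | P, Q
        for m in range(M):
            i = ind_idx[m]
            tot = 0.0
            for k in range(K):
                w = Q[i, k] * P[k, flat_la[m]]
                logp[k] = w
                tot += w
            if tot <= 0.0:
                Z[m] = np.random.randint(0, K)
            else:
                u = np.random.random() * tot
                acc = 0.0
                pick = K - 1
                for k in range(K):
                    acc += logp[k]
                    if u <= acc:
                        pick = k
                        break
                Z[m] = pick
        # --- alpha | Q (random-walk Metropolis)
        if K > 1 and no_admixture == 0:
            prop = alpha + np.random.normal(0.0, alpha_sd)
            if 0.0 < prop <= alpha_max:
                logq = 0.0
                for i in range(n):
                    for k in range(K):
                        q = Q[i, k]
                        logq += math.log(q if q > 1e-300 else 1e-300)
                cur = n * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) + (alpha - 1.0) * logq
                new = n * (math.lgamma(K * prop) - K * math.lgamma(prop)) + (prop - 1.0) * logq
                if math.log(np.random.random() + 1e-300) < new - cur:
                    alpha = prop
        # --- retained-sweep accumulators
        if sweep >= burn_in:
            ll = 0.0
            for m in range(M):
                i = ind_idx[m]
                mix = 0.0
                for k in range(K):
                    mix += Q[i, k] * P[k, flat_la[m]]
                ll += math.log(mix if mix > 1e-300 else 1e-300)
            Q_sum += Q
            P_sum += P
            alpha_sum += alpha
            ll_sum += ll
            ll_sq += ll * ll
            kept += 1

    Q_mean = Q_sum / kept
    P_mean = P_sum / kept
    ll_mean = ll_sum / kept
    ll_var = ll_sq / kept - ll_mean * ll_mean
    if ll_var < 0.0:
        ll_var = 0.0
    return Q_mean, P_mean, alpha_sum / kept, ll_mean, ll_var
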