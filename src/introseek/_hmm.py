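"""Numba kernels for the two-state introgression HMM.

Hidden states: 0 = modern-human (AMH) ancestry, 1 = archaic ancestry.
Observation symbols 0..3 encode the four per-SNP marker classes
(test-specific, archaic marker, AMH marker, common).  The transition
probability between adjacent sites separated by ``d`` Morgans follows the
pulse-admixture Markov model

    P(0->1) = alpha * (1 - exp(-T d)),   P(1->0) = (1-alpha) * (1 - exp(-T d)),

whose stationary distribution is (1-alpha, alpha).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _step_probs(d, alpha, T):
    q = 1.0 - np.exp(-T * d)
    p01 = alpha * q
    p10 = (1.0 - alpha) * q
    return 1.0 - p01, p01, p10, 1.0 - p10


@njit(cache=True)
def forward_loglik(obs, d, alpha, T, emis):
    """Scaled forward pass; returns log P(observations)."""
    n = obs.shape[0]
    a0 = (1.0 - alpha) * emis[0, obs[0]]
    a1 = alpha * emis[1, obs[0]]
    c = a0 + a1
    ll = np.log(c)
    a0 /= c
    a1 /= c
    for t in range(1, n):
        p00, p01, p10, p11 = _step_probs(d[t - 1], alpha, T)
        b0 = (a0 * p00 + a1 * p10) * emis[0, obs[t]]
        b1 = (a0 * p01 + a1 * p11) * emis[1, obs[t]]
        c = b0 + b1
        ll += np.log(c)
        a0 = b0 / c
        a1 = b1 / c
    return ll


@njit(cache=True)
def forward_backward(obs, d, alpha, T, emis, gamma_out):
    """Forward-backward for one haplotype.

    Fills ``gamma_out`` (n_sites, 2) with posteriors and returns
    (loglik, e01, e10, counts) where e01/e10 are the expected numbers of
    AMH->archaic / archaic->AMH transitions and ``counts[i, k]`` is the
    posterior-weighted count of observation k under hidden state i.
    """
    n = obs.shape[0]
    af = np.empty((n, 2))
    cs = np.empty(n)
    a0 = (1.0 - alpha) * emis[0, obs[0]]
    a1 = alpha * emis[1, obs[0]]
    c = a0 + a1
    cs[0] = c
    af[0, 0] = a0 / c
    af[0, 1] = a1 / c
    for t in range(1, n):
        p00, p01, p10, p11 = _step_probs(d[t - 1], alpha, T)
        b0 = (af[t - 1, 0] * p00 + af[t - 1, 1] * p10) * emis[0, obs[t]]
        b1 = (af[t - 1, 0] * p01 + af[t - 1, 1] * p11) * emis[1, obs[t]]
        c = b0 + b1
        cs[t] = c
        af[t, 0] = b0 / c
        af[t, 1] = b1 / c
    ll = np.sum(np.log(cs))

    counts = np.zeros((2, 4))
    e01 = 0.0
    e10 = 0.0
    b0 = 1.0
    b1 = 1.0
    gamma_out[n - 1, 0] = af[n - 1, 0]
    gamma_out[n - 1, 1] = af[n - 1, 1]
    counts[0, obs[n - 1]] += gamma_out[n - 1, 0]
    counts[1, obs[n - 1]] += gamma_out[n - 1, 1]
    for t in range(n - 2, -1, -1):
        p00, p01, p10, p11 = _step_probs(d[t], alpha, T)
        e0 = emis[0, obs[t + 1]] * b0
        e1 = emis[1, obs[t + 1]] * b1
        # pairwise posteriors (normalized per step)
        x00 = af[t, 0] * p00 * e0
        x01 = af[t, 0] * p01 * e1
        x10 = af[t, 1] * p10 * e0
        x11 = af[t, 1] * p11 * e1
        z = x00 + x01 + x10 + x11
        e01 += x01 / z
        e10 += x10 / z
        nb0 = (p00 * e0 + p01 * e1) / cs[t + 1]
        nb1 = (p10 * e0 + p11 * e1) / cs[t + 1]
        b0 = nb0
        b1 = nb1
        g0 = af[t, 0] * b0
        g1 = af[t, 1] * b1
        zg = g0 + g1
        gamma_out[t, 0] = g0 / zg
        gamma_out[t, 1] = g1 / zg
        counts[0, obs[t]] += gamma_out[t, 0]
        counts[1, obs[t]] += gamma_out[t, 1]
    return ll, e01, e10, counts


@njit(cache=True)
def viterbi(obs, d, alpha, T, emis):
    """Most probable hidden path (int8 array of 0/1)."""
    n = obs.shape[0]
    lemis = np.log(emis + 1e-300)
    back = np.zeros((n, 2), dtype=np.int8)
    v0 = np.log(1.0 - alpha) + lemis[0, obs[0]]
    v1 = np.log(alpha) + lemis[1, obs[0]]
    for t in range(1, n):
        p00, p01, p10, p11 = _step_probs(d[t - 1], alpha, T)
        l00 = np.log(p00 + 1e-300)
        l01 = np.log(p01 + 1e-300)
        l10 = np.log(p10 + 1e-300)
        l11 = np.log(p11 + 1e-300)
        # to state 0
        if v0 + l00 >= v1 + l10:
            n0 = v0 + l00
            back[t, 0] = 0
        else:
            n0 = v1 + l10
            back[t, 0] = 1
        # to state 1; tie broken toward AMH origin (shorter archaic run)
        if v1 + l11 > v0 + l01:
            n1 = v1 + l11
            back[t, 1] = 1
        else:
            n1 = v0 + l01
            back[t, 1] = 0
        v0 = n0 + lemis[0, obs[t]]
        v1 = n1 + lemis[1, obs[t]]
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = 0 if v0 >= v1 else 1
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def pooled_estep(obs_mat, d, alpha, T, emis, gammas):
    """E-step pooled over haplotypes (rows of obs_mat).

    ``gammas`` has shape (n_hap, n_sites, 2) and is filled in place.
    Returns (total loglik, e01, e10, counts).
    """
    H = obs_mat.shape[0]
    ll = 0.0
    e01 = 0.0
    e10 = 0.0
    counts = np.zeros((2, 4))
    for h in range(H):
        l, a, b, cnt = forward_backward(obs_mat[h], d, alpha, T, emis, gammas[h])
        ll += l
        e01 += a
        e10 += b
        counts += cnt
    return ll, e01, e10, counts


@njit(cache=True)
def pooled_viterbi_switches(obs_mat, d, alpha, T, emis):
    """Total number of ancestry switches on the MAP paths of all haplotypes.

    Unlike the posterior junction expectation, the MAP switch count is
    immune to micro-flicker at isolated diagnostic sites and yields a
    robust moment estimate of the introgression time T.
    """
    H = obs_mat.shape[0]
    total = 0
    for h in range(H):
        path = viterbi(obs_mat[h], d, alpha, T, emis)
        for t in range(1, path.shape[0]):
            if path[t] != path[t - 1]:
                total += 1
    return total


@njit(cache=True)
def pooled_loglik(obs_mat, d, alpha, T, emis):
    H = obs_mat.shape[0]
    ll = 0.0
    for h in range(H):
        ll += forward_loglik(obs_mat[h], d, alpha, T, emis)
    return ll
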