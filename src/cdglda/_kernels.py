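"""Numba-compiled inner loops for the collapsed Gibbs samplers.

Both kernels mutate the assignment and count arrays in place.  Randomness
enters only through the pre-drawn uniform variates ``u`` (one per token or
group), so a sweep is a deterministic function of its inputs; tests exploit
this by replaying the same variates through a pure-Python reference sweep.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lda_sweep(z, tok_day, tok_word, ndk, nkv, nk, alpha, beta, beta_sum, u):
    """One sweep of standard collapsed Gibbs over individual tokens.

    For each token (in corpus order) the current assignment is removed from
    the counts, a topic is drawn from the collapsed conditional
    ``(N_k^(v)+β_v)/(N_k+Σβ) · (N_d^(k)+α_k)``, and the counts restored.
    """
    K = nk.shape[0]
    w = np.empty(K)
    for t in range(z.shape[0]):
        d = tok_day[t]
        v = tok_word[t]
        k_old = z[t]
        ndk[d, k_old] -= 1
        nkv[k_old, v] -= 1
        nk[k_old] -= 1
        total = 0.0
        for k in range(K):
            wk = (nkv[k, v] + beta[v]) / (nk[k] + beta_sum) * (ndk[d, k] + alpha[k])
            total += wk
            w[k] = total
        r = u[t] * total
        k_new = K - 1
        for k in range(K):
            if r < w[k]:
                k_new = k
                break
        z[t] = k_new
        ndk[d, k_new] += 1
        nkv[k_new, v] += 1
        nk[k_new] += 1


@njit(cache=True)
def cdg_sweep(zg, grp_day, grp_word, grp_mult, ndk, nkv, nk,
              alpha, beta, beta_sum, allowed, u):
    """One sweep of group-constrained collapsed Gibbs.

    Each group (all A copies of one activity within one day) is moved
    atomically: its A tokens are removed from the counts, a single topic is
    drawn for the whole group from the gamma-ratio conditional

        w_k = prod_{j=0}^{A-1} (N_d^(k)+α_k+j)(N_k^(v)+β_v+j)/(N_k+Σβ+j)

    restricted to the topics where ``allowed[k, v]`` is true (the activity's
    relevant topic list), and the A tokens are re-inserted under it.
    Weights accumulate in log space to keep long products stable.
    """
    K = nk.shape[0]
    logw = np.empty(K)
    for g in range(zg.shape[0]):
        d = grp_day[g]
        v = grp_word[g]
        A = grp_mult[g]
        k_old = zg[g]
        ndk[d, k_old] -= A
        nkv[k_old, v] -= A
        nk[k_old] -= A
        maxlw = -1e300
        for k in range(K):
            if not allowed[k, v]:
                logw[k] = -1e300
                continue
            lw = 0.0
            for j in range(A):
                lw += (np.log(ndk[d, k] + alpha[k] + j)
                       + np.log(nkv[k, v] + beta[v] + j)
                       - np.log(nk[k] + beta_sum + j))
            logw[k] = lw
            if lw > maxlw:
                maxlw = lw
        total = 0.0
        for k in range(K):
            if logw[k] > -1e299:
                logw[k] = np.exp(logw[k] - maxlw)
            else:
                logw[k] = 0.0
            total += logw[k]
            logw[k] = total
        r = u[g] * total
        k_new = -1
        for k in range(K):
            if logw[k] > 0.0 and (k_new < 0):
                k_new = k  # first allowed topic as fallback
        for k in range(K):
            if r < logw[k] and allowed[k, v]:
                k_new = k
                break
        zg[g] = k_new
        ndk[d, k_new] += A
        nkv[k_new, v] += A
        nk[k_new] += A
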