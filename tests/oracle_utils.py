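"""Independent oracles for the samplers.

The sequential Polya-urn product gives the exact collapsed joint
P(Z, A | α, β) without gamma functions: processing tokens in any fixed
order, each token contributes its predictive probability given the counts
of the tokens before it.  This derivation shares no code path with the
package's gamma-ratio conditionals, so agreement is evidence, not
tautology.
"""

import numpy as np


def urn_log_prob(tok_day, tok_word, z, D, K, V, alpha, beta):
    """Exact log P(Z, A | α, β) via the sequential predictive product."""
    ndk = np.zeros((D, K))
    nkv = np.zeros((K, V))
    nk = np.zeros(K)
    nd = np.zeros(D)
    a_sum, b_sum = alpha.sum(), beta.sum()
    lp = 0.0
    for d, v, k in zip(tok_day, tok_word, z):
        lp += np.log((ndk[d, k] + alpha[k]) / (nd[d] + a_sum))
        lp += np.log((nkv[k, v] + beta[v]) / (nk[k] + b_sum))
        ndk[d, k] += 1
        nkv[k, v] += 1
        nk[k] += 1
        nd[d] += 1
    return lp


def token_conditional_oracle(flat, z, i, K, hp):
    """P(z_i = k | rest) by evaluating the urn joint at each k."""
    lps = np.empty(K)
    for k in range(K):
        z_try = z.copy()
        z_try[i] = k
        lps[k] = urn_log_prob(flat.tok_day, flat.tok_word, z_try,
                              flat.D, K, flat.V, hp.alpha, hp.beta)
    p = np.exp(lps - lps.max())
    return p / p.sum()


def group_conditional_oracle(flat, zg, g, K, hp):
    """P(z_g = k | rest) under the constrained joint (Eq-5-style restriction).

    Constraint-satisfying assignments are exactly those expressible as a
    topic per group, so the restricted-and-renormalized conditional is the
    urn joint evaluated at each group topic, normalized over k.
    """
    lps = np.empty(K)
    for k in range(K):
        zg_try = zg.copy()
        zg_try[g] = k
        z = np.repeat(zg_try, flat.grp_mult)
        lps[k] = urn_log_prob(flat.tok_day, flat.tok_word, z,
                              flat.D, K, flat.V, hp.alpha, hp.beta)
    p = np.exp(lps - lps.max())
    return p / p.sum()


def random_tiny_flat(rng, max_groups=4, max_k=3, max_v=3, max_mult=3):
    """A random tiny corpus (as FlatCorpus) plus random hyperparams."""
    from cdglda.corpus import BillingRecord, build_corpus
    from cdglda.lda import FlatCorpus, Hyperparams

    n_groups = int(rng.integers(2, max_groups + 1))
    records = []
    for _ in range(n_groups):
        records.append(BillingRecord(
            "T", f"v{rng.integers(0, max_v)}",
            int(rng.integers(1, max_mult + 1)), int(rng.integers(0, 2))))
    corpus, _ = build_corpus(records)
    flat = FlatCorpus(corpus)
    K = int(rng.integers(2, max_k + 1))
    hp = Hyperparams(K=K, alpha=rng.uniform(0.3, 2.0, K),
                     beta=rng.uniform(0.01, 1.0, corpus.V))
    return flat, hp
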