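"""Standard collapsed-Gibbs latent Dirichlet allocation over clinical days.

The clinical day plays the role of the document and the clinical activity
the role of the word.  The generative story: draw a topic-activity
distribution φ_k ~ Dir(β) for each topic, a day-topic distribution
θ_d ~ Dir(α) for each day, then for every token draw a topic z ~ Multi(θ_d)
and an activity a ~ Multi(φ_z).  Inference collapses φ and θ and samples
token assignments from

    P(z_i = k | Z_¬i, A) ∝ (N_k^(v)+β_v)/(Σ_v N_k^(v)+β_v) · (N_d^(k)+α_k).

This module is both the comparator model and the correctness anchor for the
group-constrained sampler: a group of multiplicity 1 must reduce to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .corpus import Corpus

__all__ = [
    "Hyperparams",
    "FlatCorpus",
    "CountState",
    "TopicEstimates",
    "init_assignments",
    "token_conditional",
    "gibbs_sweep",
    "estimate",
    "joint_log_prob",
    "run_lda",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class Hyperparams:
    """Topic count and Dirichlet priors (stored as vectors; may be asymmetric)."""

    K: int
    alpha: np.ndarray  # length K, positive
    beta: np.ndarray   # length V, positive

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if alpha.shape != (self.K,) or np.any(alpha <= 0):
            raise ValueError("alpha must be a length-K positive vector")
        if beta.ndim != 1 or np.any(beta <= 0):
            raise ValueError("beta must be a positive vector of length V")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @classmethod
    def symmetric(cls, K: int, V: int, alpha: float = 1.0, beta: float = 0.01):
        """Symmetric priors; defaults α=1.0, β=0.01."""
        return cls(K=K, alpha=np.full(K, float(alpha)), beta=np.full(V, float(beta)))

    @property
    def beta_sum(self) -> float:
        return float(self.beta.sum())


class FlatCorpus:
    """Array view of a corpus: per-token and per-group index vectors.

    Tokens are laid out day by day, group by group (groups sorted by
    activity index), each group's tokens contiguous; both samplers and all
    count bookkeeping run on these arrays.
    """

    def __init__(self, corpus: Corpus):
        tok_day, tok_word = [], []
        grp_day, grp_word, grp_mult, grp_start = [], [], [], []
        for d, day in enumerate(corpus.days):
            for v, a in day.groups:
                grp_day.append(d)
                grp_word.append(v)
                grp_mult.append(a)
                grp_start.append(len(tok_day))
                tok_day.extend([d] * a)
                tok_word.extend([v] * a)
        self.tok_day = np.asarray(tok_day, dtype=np.int64)
        self.tok_word = np.asarray(tok_word, dtype=np.int64)
        self.grp_day = np.asarray(grp_day, dtype=np.int64)
        self.grp_word = np.asarray(grp_word, dtype=np.int64)
        self.grp_mult = np.asarray(grp_mult, dtype=np.int64)
        self.grp_start = np.asarray(grp_start, dtype=np.int64)
        self.D = corpus.D
        self.V = corpus.V

    @property
    def n_tokens(self) -> int:
        return self.tok_day.shape[0]

    @property
    def n_groups(self) -> int:
        return self.grp_day.shape[0]


@dataclass
class CountState:
    """Sufficient statistics of a token assignment.

    ``ndk[d, k]`` — tokens of day d on topic k; ``nkv[k, v]`` — tokens of
    activity v on topic k; ``nk`` and ``nd`` the corresponding margins;
    ``z`` the per-token assignments.
    """

    ndk: np.ndarray
    nkv: np.ndarray
    nk: np.ndarray
    nd: np.ndarray
    z: np.ndarray

    @classmethod
    def from_assignments(cls, flat: FlatCorpus, z: np.ndarray, K: int) -> "CountState":
        z = np.asarray(z, dtype=np.int64)
        ndk = np.zeros((flat.D, K), dtype=np.int64)
        nkv = np.zeros((K, flat.V), dtype=np.int64)
        np.add.at(ndk, (flat.tok_day, z), 1)
        np.add.at(nkv, (z, flat.tok_word), 1)
        return cls(ndk=ndk, nkv=nkv, nk=nkv.sum(axis=1), nd=ndk.sum(axis=1), z=z)

    def check(self) -> None:
        """Assert the count invariants; cheap enough to run after every sweep in tests."""
        assert np.all(self.ndk >= 0) and np.all(self.nkv >= 0)
        assert np.array_equal(self.ndk.sum(axis=1), self.nd)
        assert np.array_equal(self.nkv.sum(axis=1), self.nk)
        assert self.nk.sum() == self.nd.sum() == self.z.shape[0]

    def copy(self) -> "CountState":
        return CountState(self.ndk.copy(), self.nkv.copy(), self.nk.copy(),
                          self.nd.copy(), self.z.copy())


@dataclass
class TopicEstimates:
    """Posterior-mean point estimates: φ (K×V) and θ (D×K), row-stochastic."""

    phi: np.ndarray
    theta: np.ndarray


def init_assignments(corpus_or_flat, hp: Hyperparams, seed: int) -> CountState:
    """Assign every token a uniform random topic; counts built to match."""
    flat = corpus_or_flat if isinstance(corpus_or_flat, FlatCorpus) else FlatCorpus(corpus_or_flat)
    if flat.n_tokens == 0:
        raise ValueError("corpus has no tokens")
    rng = np.random.default_rng(seed)
    z = rng.integers(0, hp.K, size=flat.n_tokens)
    return CountState.from_assignments(flat, z, hp.K)


def token_conditional(state: CountState, hp: Hyperparams, d: int, v: int) -> np.ndarray:
    """Unnormalized collapsed conditional for one token of activity v in day d.

    The counts in ``state`` must already exclude the token being resampled
    (the ``¬z_{d,i}`` convention).
    """
    return ((state.nkv[:, v] + hp.beta[v]) / (state.nk + hp.beta_sum)
            * (state.ndk[d, :] + hp.alpha))


def gibbs_sweep(state: CountState, hp: Hyperparams, flat: FlatCorpus,
                rng: np.random.Generator) -> CountState:
    """Resample every token once, in corpus order.  Mutates and returns ``state``."""
    u = rng.random(flat.n_tokens)
    _kernels.lda_sweep(state.z, flat.tok_day, flat.tok_word,
                       state.ndk, state.nkv, state.nk,
                       hp.alpha, hp.beta, hp.beta_sum, u)
    return state


def estimate(state: CountState, hp: Hyperparams) -> TopicEstimates:
    """Smoothed point estimates φ_k^(v) = (N_k^(v)+β_v)/(N_k+Σβ), θ likewise."""
    phi = (state.nkv + hp.beta) / (state.nk + hp.beta_sum)[:, None]
    theta = (state.ndk + hp.alpha) / (state.nd + hp.alpha.sum())[:, None]
    return TopicEstimates(phi=phi, theta=theta)


def joint_log_prob(state: CountState, hp: Hyperparams) -> float:
    """Log of the collapsed joint P(Z, A | α, β) up to an assignment-independent constant.

    log Σ_{d,k} Γ(N_d^(k)+α_k) + Σ_k [ Σ_v Γ(N_k^(v)+β_v) − Γ(N_k+Σβ) ].
    Used as the scoring function of the brute-force enumeration oracle.
    """
    day_part = gammaln(state.ndk + hp.alpha).sum()
    topic_part = gammaln(state.nkv + hp.beta).sum() - gammaln(state.nk + hp.beta_sum).sum()
    return float(day_part + topic_part)


def run_lda(corpus: Corpus, hp: Hyperparams, seed: int,
            sweeps: int = 1000, burn_in: int = 500, average: bool = False):
    """Fit baseline LDA; returns ``(CountState, TopicEstimates)``.

    By default φ/θ come from the single final state (reproducible given the
    seed); with ``average=True`` the post-burn-in sweeps' estimates are
    averaged instead.
    """
    flat = FlatCorpus(corpus)
    state = init_assignments(flat, hp, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    phi_acc = theta_acc = None
    n_acc = 0
    for sweep in range(sweeps):
        gibbs_sweep(state, hp, flat, rng)
        if average and sweep >= burn_in:
            est = estimate(state, hp)
            phi_acc = est.phi if phi_acc is None else phi_acc + est.phi
            theta_acc = est.theta if theta_acc is None else theta_acc + est.theta
            n_acc += 1
    if average and n_acc:
        return state, TopicEstimates(phi=phi_acc / n_acc, theta=theta_acc / n_acc)
    return state, estimate(state, hp)


def save_checkpoint(path, state: CountState, hp: Hyperparams, seed: int,
                    extra: dict | None = None) -> None:
    """JSON checkpoint (assignments + hyperparams + seed) for exact resume."""
    payload = {
        "seed": seed,
        "K": hp.K,
        "alpha": hp.alpha.tolist(),
        "beta": hp.beta.tolist(),
        "z": state.z.tolist(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, corpus: Corpus):
    """Rebuild ``(CountState, Hyperparams, payload)`` from a checkpoint."""
    with open(path) as fh:
        payload = json.load(fh)
    hp = Hyperparams(K=payload["K"], alpha=np.asarray(payload["alpha"]),
                     beta=np.asarray(payload["beta"]))
    flat = FlatCorpus(corpus)
    state = CountState.from_assignments(flat, np.asarray(payload["z"]), hp.K)
    return state, hp, payload
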