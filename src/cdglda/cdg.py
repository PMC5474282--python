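"""Group-constrained collapsed Gibbs LDA with topic correlation limitation.

Two clinical observations motivate the model.  First, repeated occurrences
of one activity within one hospitalized day serve one clinical goal, so all
tokens of a (day, activity) *group* are forced to share a topic: the
sampler moves groups atomically, drawing the group topic from the collapsed
conditional of the constrained joint

    w_k = ∏_{j=0}^{A-1} (N_d,¬^(k)+α_k+j) · (N_k,¬^(v)+β_v+j) / (N_k,¬+Σβ+j),

where A is the group multiplicity and the ¬ counts exclude the whole group.
Setting A = 1 recovers the standard per-token conditional.

Second, an activity should correlate with few topics — the more informative
the activity (higher IDF over clinical days), the fewer.  Each activity v
keeps a *relevant topic list* κ(v) with a target size s(v) mapped from its
IDF; every δ sweeps the topic with the smallest relevant value
RV(k, v) = N_k^(v) / rank(k, v) is discarded from κ(v) until |κ(v)| = s(v),
and sampling for v's groups is restricted to κ(v).  For reporting, topic
rankings are recomputed under the IDF-adjusted φ̄_k^(v) = φ_k^(v)·IDF(v) so
ubiquitous, uninformative activities stop dominating every top list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import _kernels
from .corpus import Corpus
from .lda import CountState, FlatCorpus, Hyperparams, TopicEstimates, estimate

__all__ = [
    "LimitationState",
    "AdjustedEstimates",
    "CDGResult",
    "group_conditional",
    "init_group_assignments",
    "constrained_sweep",
    "compute_idf",
    "compute_s",
    "compute_rv",
    "update_relevant_lists",
    "adjusted_phi",
    "run_cdg",
]


@dataclass
class LimitationState:
    """Per-activity topic-correlation limitation state.

    ``allowed[k, v]`` is the membership mask of the relevant topic list
    κ(v); ``s[v]`` its target size; ``idf[v]`` the informativeness weight.
    ``history`` records each removal as ``(sweep, v, topic)``.
    """

    idf: np.ndarray           # (V,)
    s: np.ndarray             # (V,) ints in [1, K]
    allowed: np.ndarray       # (K, V) bool
    delta: int = 300
    history: list = field(default_factory=list)

    @classmethod
    def full(cls, idf: np.ndarray, s: np.ndarray, K: int, delta: int = 300):
        V = idf.shape[0]
        return cls(idf=idf, s=s, allowed=np.ones((K, V), dtype=bool), delta=delta)

    def kappa(self, v: int) -> np.ndarray:
        """Relevant topic list of activity v (sorted topic indices)."""
        return np.flatnonzero(self.allowed[:, v])

    @property
    def sizes(self) -> np.ndarray:
        return self.allowed.sum(axis=0)

    @property
    def done(self) -> bool:
        return bool(np.all(self.sizes <= self.s))


@dataclass
class AdjustedEstimates:
    """IDF-adjusted topic-activity scores and the per-topic activity rankings."""

    phi_bar: np.ndarray        # (K, V) = phi * idf
    order_phi: np.ndarray      # (K, V) activity indices, best first, under phi
    order_phi_bar: np.ndarray  # same under phi_bar


@dataclass
class CDGResult:
    """Everything a fit produces: counts, limitation state, estimates, group topics."""

    state: CountState
    limitation: LimitationState
    estimates: TopicEstimates
    adjusted: AdjustedEstimates
    zg: np.ndarray


def group_conditional(state: CountState, hp: Hyperparams, d: int, v: int,
                      A: int, support) -> np.ndarray:
    """Unnormalized constrained conditional for a whole group.

    ``state`` must exclude all A tokens of the group (the ``¬z_d^g``
    convention).  Returns one weight per topic in ``support``, computed in
    log space and exponentiated.
    """
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("support must be nonempty")
    j = np.arange(A)
    logw = np.empty(support.shape[0])
    for i, k in enumerate(support):
        logw[i] = (np.log(state.ndk[d, k] + hp.alpha[k] + j).sum()
                   + np.log(state.nkv[k, v] + hp.beta[v] + j).sum()
                   - np.log(state.nk[k] + hp.beta_sum + j).sum())
    return np.exp(logw)


def init_group_assignments(flat: FlatCorpus, hp: Hyperparams, seed: int):
    """Uniform random topic per group; returns ``(CountState, zg)``."""
    rng = np.random.default_rng(seed)
    zg = rng.integers(0, hp.K, size=flat.n_groups)
    z = np.repeat(zg, flat.grp_mult)
    return CountState.from_assignments(flat, z, hp.K), zg


def constrained_sweep(state: CountState, hp: Hyperparams, flat: FlatCorpus,
                      limitation: LimitationState, zg: np.ndarray,
                      rng: np.random.Generator) -> None:
    """Resample every group once from its relevant topic list.

    All tokens of a group move atomically; a group whose current topic was
    pruned from κ(v) keeps its counts until this, its next scheduled
    resample, at which point the pruned topic is simply absent from the
    support.  ``state`` and ``zg`` are mutated in place.
    """
    u = rng.random(flat.n_groups)
    _kernels.cdg_sweep(zg, flat.grp_day, flat.grp_word, flat.grp_mult,
                       state.ndk, state.nkv, state.nk,
                       hp.alpha, hp.beta, hp.beta_sum,
                       limitation.allowed, u)
    state.z[:] = np.repeat(zg, flat.grp_mult)


def compute_idf(corpus: Corpus) -> np.ndarray:
    """IDF(v) = ln(D / #days containing v); 0 for ubiquitous activities."""
    df = np.zeros(corpus.V, dtype=np.int64)
    for day in corpus.days:
        for v, _ in day.groups:
            df[v] += 1
    if np.any(df == 0):
        raise ValueError("vocabulary contains activities absent from the corpus")
    return np.log(corpus.D / df)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def compute_s(idf: np.ndarray, K: int, mode: str = "linear") -> np.ndarray:
    """Map informativeness to the topic-number upper bound s(v) ∈ [1, K].

    Monotone non-increasing in IDF: the most informative activity gets
    s = 1, the least informative s = K.  ``"linear"`` (default) rescales the
    IDF range onto [K, 1] with half-up rounding; ``"rank"`` uses the
    activity's IDF quantile instead, which is insensitive to outliers.  A
    constant IDF vector degenerates to s ≡ K (no restriction signal).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    idf = np.asarray(idf, dtype=float)
    lo, hi = idf.min(), idf.max()
    if hi == lo:
        return np.full(idf.shape[0], K, dtype=np.int64)
    if mode == "linear":
        s = _round_half_up(K + (idf - lo) / (hi - lo) * (1.0 - K))
    elif mode == "rank":
        q = (rankdata(idf, method="average") - 1.0) / (idf.shape[0] - 1.0)
        s = _round_half_up(K - q * (K - 1.0))
    else:
        raise ValueError(f"unknown s-mapping mode {mode!r}")
    return np.clip(s, 1, K)


def compute_rv(state: CountState, estimates: TopicEstimates) -> np.ndarray:
    """Relevant value RV(k, v) = N_k^(v) / rank(k, v).

    rank(k, v) is the 1-based position of v within topic k when activities
    are sorted by φ_k descending, ties broken by activity index ascending.
    """
    K, V = estimates.phi.shape
    rank = np.empty((K, V), dtype=np.int64)
    idx = np.arange(V)
    for k in range(K):
        order = np.lexsort((idx, -estimates.phi[k]))
        rank[k, order] = idx + 1
    return state.nkv / rank


def update_relevant_lists(limitation: LimitationState, rv: np.ndarray,
                          sweep: int | None = None) -> list:
    """One pruning step: drop the least-relevant topic from each oversized list.

    For every activity with |κ(v)| > s(v), the single topic in κ(v) with the
    minimum RV(k, v) is removed (ties go to the lowest topic index); lists
    already at or below target are frozen.  Returns the removals as
    ``(v, topic)`` pairs, also appended to ``limitation.history``.
    """
    removed = []
    sizes = limitation.sizes
    for v in np.flatnonzero(sizes > limitation.s):
        ks = np.flatnonzero(limitation.allowed[:, v])
        k_drop = ks[np.argmin(rv[ks, v])]  # argmin returns first min -> lowest index
        limitation.allowed[k_drop, v] = False
        removed.append((int(v), int(k_drop)))
        limitation.history.append((sweep, int(v), int(k_drop)))
    return removed


def adjusted_phi(estimates: TopicEstimates, idf: np.ndarray) -> AdjustedEstimates:
    """φ̄ = φ·IDF elementwise, with per-topic rankings under both scores."""
    phi = estimates.phi
    if phi.shape[1] != idf.shape[0]:
        raise ValueError("phi and idf dimensions disagree")
    phi_bar = phi * idf
    idx = np.arange(phi.shape[1])
    order_phi = np.vstack([np.lexsort((idx, -row)) for row in phi])
    order_phi_bar = np.vstack([np.lexsort((idx, -row)) for row in phi_bar])
    return AdjustedEstimates(phi_bar=phi_bar, order_phi=order_phi,
                             order_phi_bar=order_phi_bar)


def run_cdg(corpus: Corpus, hp: Hyperparams, seed: int,
            total_sweeps: int = 1000, delta: int = 300, burn_in: int = 200,
            s_mode: str = "linear") -> CDGResult:
    """Fit CDG-LDA: constrained sweeps with a list-pruning step every δ sweeps.

    Pruning starts after ``burn_in`` sweeps and repeats every ``delta``
    sweeps, removing at most one topic per activity per step; the final
    pruning step is never scheduled on the last sweep, so every surviving
    group topic lies inside its activity's final relevant list.
    """
    flat = FlatCorpus(corpus)
    idf = compute_idf(corpus)
    s = compute_s(idf, hp.K, mode=s_mode)
    limitation = LimitationState.full(idf, s, hp.K, delta=delta)

    needed = int(hp.K - s.min())
    n_updates = 0 if total_sweeps <= burn_in else (total_sweeps - 1 - burn_in) // delta + 1
    if n_updates < needed:
        warnings.warn(
            f"{total_sweeps} sweeps allow only {n_updates} pruning updates; "
            f"{needed} needed for all relevant lists to reach their target size",
            stacklevel=2,
        )

    state, zg = init_group_assignments(flat, hp, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    for sweep in range(1, total_sweeps + 1):
        constrained_sweep(state, hp, flat, limitation, zg, rng)
        due = sweep >= burn_in and (sweep - burn_in) % delta == 0
        if due and sweep < total_sweeps and not limitation.done:
            rv = compute_rv(state, estimate(state, hp))
            update_relevant_lists(limitation, rv, sweep=sweep)
    est = estimate(state, hp)
    adj = adjusted_phi(est, idf)
    return CDGResult(state=state, limitation=limitation, estimates=est,
                     adjusted=adj, zg=zg)
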