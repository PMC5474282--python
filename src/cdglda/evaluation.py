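"""Topic-quality metrics and topic-number selection.

Covers the quantities used to judge discovered clinical-goal topics:
redundancy (RE) of the union of per-topic top-N activity lists, the
discounted human-relevance score NKQM@N, model perplexity, per-day topic
labels, and the perplexity/label-size trade-off for choosing K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .lda import Hyperparams, run_lda

__all__ = [
    "TopList",
    "top_list",
    "redundancy",
    "nkqm",
    "read_scores",
    "perplexity",
    "label_size",
    "select_k",
]


@dataclass
class TopList:
    """Per-topic top-N activity lists.  ``lists[k]`` holds activity ids, best first."""

    lists: list
    N: int


def top_list(scores: np.ndarray, N: int) -> TopList:
    """Top-N activities per topic under a K×V score matrix (φ or φ̄).

    Ties broken by activity index ascending, matching the sampler's ranking
    convention.
    """
    K, V = scores.shape
    n = min(N, V)
    idx = np.arange(V)
    lists = [list(np.lexsort((idx, -scores[k]))[:n]) for k in range(K)]
    return TopList(lists=lists, N=N)


def redundancy(toplist: TopList) -> int:
    """RE = Σ_{v ∈ Ω(T)} (count(v) − 1) over the union T of all top-N lists.

    count(v) is the number of topics whose list contains v; fully disjoint
    lists give RE = 0, so lower is better (more distinctive topics).
    """
    counts: dict = {}
    for lst in toplist.lists:
        for v in set(lst):
            counts[v] = counts.get(v, 0) + 1
    return sum(c - 1 for c in counts.values())


def nkqm(scores, N: int | None = None) -> float:
    """Discounted, normalized relevance of ranked topic lists, in [0, 1].

    ``scores[k][j]`` is the human relevance (0 irrelevant / 1 relevant /
    2 very relevant) of the activity at 1-based position j+1 of topic k.

        NKQM@N = (1/K) Σ_k [ Σ_{j=1}^N score_{k,j} / ln(j+1) ] / Z_N,

    with Z_N = Σ_j 2/ln(j+1) the ideal (all-2) inner sum, so a perfect
    ranking scores exactly 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be K x N")
    if N is not None:
        scores = scores[:, :N]
    if not np.all(np.isin(scores, (0.0, 1.0, 2.0))):
        raise ValueError("relevance scores must be 0, 1 or 2")
    n = scores.shape[1]
    discount = 1.0 / np.log(np.arange(1, n + 1) + 1.0)
    z = 2.0 * discount.sum()
    return float(np.mean(scores @ discount) / z)


def read_scores(path, K: int, N: int) -> np.ndarray:
    """Load a K×N relevance-score matrix from TSV columns (topic, position, activity, score)."""
    df = pd.read_csv(path, sep="\t")
    out = np.zeros((K, N))
    for _, row in df.iterrows():
        k, j = int(row["topic"]), int(row["position"])
        if 0 <= k < K and 1 <= j <= N:
            out[k, j - 1] = row["score"]
    return out


def perplexity(phi: np.ndarray, theta: np.ndarray, corpus: Corpus) -> float:
    """Reciprocal geometric mean of the per-token likelihood.

        exp( − Σ_d Σ_i ln Σ_k θ_d^(k) φ_k^(v_i) / Σ_d N_d )

    Lower is better; a model assigning every token probability 1/V has
    perplexity exactly V.
    """
    loglik = 0.0
    n_tokens = 0
    token_prob = theta @ phi  # D x V
    for d, day in enumerate(corpus.days):
        for v, a in day.groups:
            loglik += a * np.log(token_prob[d, v])
            n_tokens += a
    return float(np.exp(-loglik / n_tokens))


def label_size(theta: np.ndarray, tau_mass: float = 0.8, tau_max: int = 3):
    """Per-day topic labels and their mean size.

    A day's label is the smallest set of topics, taken in decreasing θ_d
    order, whose cumulative mass reaches ``tau_mass``, capped at ``tau_max``
    topics.  Returns ``(mean label size, list of sorted topic-id tuples)``.
    """
    theta = np.asarray(theta, dtype=float)
    labels = []
    for row in theta:
        order = np.argsort(-row, kind="stable")
        mass = 0.0
        chosen = []
        for k in order:
            chosen.append(int(k))
            mass += row[k]
            if mass >= tau_mass or len(chosen) >= tau_max:
                break
        labels.append(tuple(sorted(chosen)))
    mean_size = float(np.mean([len(l) for l in labels]))
    return mean_size, labels


def select_k(corpus: Corpus, candidates, seed: int = 0, *,
             alpha: float = 1.0, beta: float = 0.01,
             sweeps: int = 200, burn_in: int = 100,
             tau_mass: float = 0.8, tau_max: int = 3,
             fit=None) -> tuple:
    """Choose K by the perplexity / label-size trade-off.

    For each candidate K a model is fitted (baseline LDA unless ``fit`` is
    supplied) and both in-sample perplexity and mean label size recorded.
    Both curves are min-max normalized over the candidate range and the
    selected K minimizes their absolute gap — the intersection point of the
    falling perplexity curve and the rising label-size curve.  Ties go to
    the smaller K; if a curve is constant its normalized version is all
    zeros, so selection degenerates to the other curve's minimum.

    Returns ``(selected K, DataFrame with per-K metrics)``.
    """
    candidates = sorted(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate K values")
    rows = []
    for K in candidates:
        hp = Hyperparams.symmetric(K, corpus.V, alpha=alpha, beta=beta)
        if fit is None:
            _, est = run_lda(corpus, hp, seed=seed, sweeps=sweeps, burn_in=burn_in)
        else:
            est = fit(corpus, hp, seed)
        perp = perplexity(est.phi, est.theta, corpus)
        mean_size, _ = label_size(est.theta, tau_mass=tau_mass, tau_max=tau_max)
        rows.append({"K": K, "perplexity": perp, "label_size": mean_size})
    table = pd.DataFrame(rows)

    def _norm(col):
        lo, hi = col.min(), col.max()
        if hi == lo:
            return np.zeros(len(col))
        return (col - lo) / (hi - lo)

    table["norm_perplexity"] = _norm(table["perplexity"])
    table["norm_label_size"] = _norm(table["label_size"])
    table["gap"] = np.abs(table["norm_perplexity"] - table["norm_label_size"])
    selected = int(table.loc[table["gap"].idxmin(), "K"])
    return selected, table
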