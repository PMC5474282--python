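"""Synthetic billing corpora with planted topic and stage structure.

Real hospital billing extracts cannot be redistributed, so every part of
the pipeline is exercised on generated data that mimics their shape:
multiple patient traces, a run of hospitalized days per trace, several
activity groups per day with small repeat counts, a sparse planted
topic-activity matrix φ*, and (optionally) a Markov chain of treatment
stages across days driving the per-day topic mixture — the structure a
staged clinical pathway imposes.

Each group draws one true topic z* from the day's θ*, one activity from
φ*_{z*}, and a multiplicity of 1 plus a Poisson count, so the ground truth
satisfies the one-topic-per-group constraint by construction.  When a drawn
activity collides with an existing group of the same day under a different
topic, the (topic, activity) pair is redrawn; a same-topic collision merges
into the existing group, as corpus construction would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .corpus import BillingRecord, Corpus, Vocabulary, build_corpus

__all__ = [
    "StageConfig",
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate",
    "staged_traces",
    "default_stage_config",
    "write_billing_csv",
    "write_truth_json",
]


@dataclass
class StageConfig:
    """Markov chain over treatment stages with one θ* profile per stage."""

    transition: np.ndarray  # (S, S), rows sum to 1
    initial: np.ndarray     # (S,)
    profiles: np.ndarray    # (S, K) day-topic mixture for each stage

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_stages(self) -> int:
        return self.transition.shape[0]


def default_stage_config(K: int = 3) -> StageConfig:
    """Absorbing admission → treatment → re-examination chain, one dominant topic per stage."""
    S = 3
    transition = np.array([[0.6, 0.4, 0.0],
                           [0.0, 0.6, 0.4],
                           [0.0, 0.0, 1.0]])
    initial = np.array([1.0, 0.0, 0.0])
    profiles = np.full((S, K), 0.1 / max(K - 1, 1))
    for s in range(S):
        profiles[s, s % K] = 0.9
    profiles /= profiles.sum(axis=1, keepdims=True)
    return StageConfig(transition=transition, initial=initial, profiles=profiles)


@dataclass
class GeneratorConfig:
    """Shape of the generated corpus.

    Defaults mirror the magnitude of real billing datasets scaled down to
    desk size: 50 traces of 6–14 hospitalized days (≈500 clinical days),
    a 50-activity vocabulary, ~8 groups per day with multiplicity
    1 + Poisson(0.8), a sparse planted φ* (Dirichlet 0.05) and moderately
    concentrated per-day θ* (Dirichlet 0.5).
    """

    k_true: int = 3
    vocab_size: int = 50
    n_traces: int = 50
    days_range: tuple = (6, 14)
    mean_groups: float = 8.0
    mean_extra_mult: float = 0.8
    phi_concentration: float = 0.05
    theta_concentration: float = 0.5
    stages: StageConfig | None = None
    seed: int = 0


@dataclass
class SyntheticCorpus:
    """Generated corpus plus all ground truth needed for recovery tests."""

    corpus: Corpus
    vocab: Vocabulary
    phi_star: np.ndarray       # (K*, V)
    theta_star: np.ndarray     # (D, K*) in corpus day order
    group_topics: np.ndarray   # true topic per group, in FlatCorpus group order
    day_stages: np.ndarray | None  # (D,) stage index per day, or None
    config: GeneratorConfig


def _draw_day_groups(rng, theta, phi_star, n_groups, mean_extra):
    """Draw a day's groups under rejection: colliding activities must share a topic."""
    by_activity: dict = {}
    for _ in range(n_groups):
        for _attempt in range(1000):
            z = int(rng.choice(theta.shape[0], p=theta))
            v = int(rng.choice(phi_star.shape[1], p=phi_star[z]))
            if v not in by_activity or by_activity[v][0] == z:
                break
        else:  # pragma: no cover - requires pathological config
            raise RuntimeError("could not draw a constraint-consistent group")
        a = 1 + int(rng.poisson(mean_extra))
        if v in by_activity:
            by_activity[v] = (z, by_activity[v][1] + a)
        else:
            by_activity[v] = (z, a)
    return by_activity


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus with planted topics (and stages when configured)."""
    if config.mean_groups > config.vocab_size:
        raise ValueError("mean groups per day exceeds vocabulary size")
    if config.k_true < 1 or config.n_traces < 1:
        raise ValueError("k_true and n_traces must be positive")
    rng = np.random.default_rng(config.seed)
    K, V = config.k_true, config.vocab_size
    phi_star = rng.dirichlet(np.full(V, config.phi_concentration), size=K)
    # Dirichlet with tiny concentration can zero out entries in float; keep
    # every activity reachable so IDF is defined for the whole vocabulary.
    phi_star = phi_star + 1e-12
    phi_star /= phi_star.sum(axis=1, keepdims=True)

    width = len(str(config.n_traces))
    vwidth = len(str(V))
    names = [f"item_{v:0{vwidth}d}" for v in range(V)]
    vocab = Vocabulary(names)

    records = []
    theta_rows, stage_rows, topic_rows = [], [], []
    for t in range(config.n_traces):
        trace_id = f"T{t:0{width}d}"
        lo, hi = config.days_range
        n_days = int(rng.integers(lo, hi + 1))
        stage = None
        for day in range(n_days):
            if config.stages is not None:
                if stage is None:
                    stage = int(rng.choice(config.stages.n_stages, p=config.stages.initial))
                else:
                    stage = int(rng.choice(config.stages.n_stages,
                                           p=config.stages.transition[stage]))
                theta = config.stages.profiles[stage]
            else:
                theta = rng.dirichlet(np.full(K, config.theta_concentration))
            n_groups = max(1, int(rng.poisson(config.mean_groups)))
            by_activity = _draw_day_groups(rng, theta, phi_star, n_groups,
                                           config.mean_extra_mult)
            for v, (z, a) in by_activity.items():
                records.append(BillingRecord(trace_id, names[v], a, day))
            theta_rows.append(((trace_id, day), np.asarray(theta, dtype=float)))
            stage_rows.append(((trace_id, day), -1 if stage is None else stage))
            # group order within a day is by activity index, matching FlatCorpus
            topic_rows.append(((trace_id, day),
                               [z for v, (z, _) in sorted(by_activity.items())]))

    # the corpus vocabulary is the *observed* activities; under a sparse φ*
    # some of the V configured activities never occur, so the planted rows
    # are restricted to the observed columns and renormalized (the removed
    # mass is negligible by construction)
    corpus, built_vocab = build_corpus(records)
    observed = [names.index(n) for n in built_vocab]
    phi_star = phi_star[:, observed]
    phi_star /= phi_star.sum(axis=1, keepdims=True)
    # align ground truth with the corpus's (trace, day) sort order
    key_order = {(d.trace_id, d.day): i for i, d in enumerate(corpus.days)}
    theta_star = np.zeros((corpus.D, K))
    day_stages = np.full(corpus.D, -1, dtype=np.int64)
    group_topics: list = [None] * corpus.D
    for (key, theta) in theta_rows:
        theta_star[key_order[key]] = theta
    for (key, st) in stage_rows:
        day_stages[key_order[key]] = st
    for (key, topics) in topic_rows:
        group_topics[key_order[key]] = topics
    group_topics = np.asarray([z for day in group_topics for z in day], dtype=np.int64)

    return SyntheticCorpus(
        corpus=corpus, vocab=built_vocab, phi_star=phi_star,
        theta_star=theta_star, group_topics=group_topics,
        day_stages=None if config.stages is None else day_stages,
        config=config,
    )


def staged_traces(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate with an explicit stage chain (``config.stages`` required)."""
    if config.stages is None:
        raise ValueError("config.stages must be provided for staged generation")
    return generate(config)


def write_billing_csv(synth: SyntheticCorpus, path) -> None:
    """Write the standard four-column billing CSV consumed by corpus ingestion."""
    with open(path, "w") as fh:
        fh.write("trace_id,item_name,amount,day\n")
        for day in synth.corpus.days:
            for v, a in day.groups:
                fh.write(f"{day.trace_id},{synth.vocab.name(v)},{a},{day.day}\n")


def write_truth_json(synth: SyntheticCorpus, path) -> None:
    """Ground truth (φ*, θ*, group topics, stages) as JSON."""
    payload = {
        "phi_star": synth.phi_star.tolist(),
        "theta_star": synth.theta_star.tolist(),
        "group_topics": synth.group_topics.tolist(),
        "day_stages": None if synth.day_stages is None else synth.day_stages.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
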