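import numpy as np
import pytest
from oracle_utils import group_conditional_oracle, random_tiny_flat

from cdglda.cdg import (LimitationState, adjusted_phi, compute_idf, compute_rv,
                        compute_s, constrained_sweep, group_conditional,
                        init_group_assignments, run_cdg, update_relevant_lists)
from cdglda.corpus import BillingRecord, build_corpus
from cdglda.lda import (CountState, FlatCorpus, Hyperparams, TopicEstimates,
                        estimate, token_conditional)


@pytest.fixture()
def small(small_synth):
    flat = FlatCorpus(small_synth.corpus)
    hp = Hyperparams.symmetric(3, small_synth.corpus.V)
    return flat, hp


def _full_limitation(flat, K, delta=300):
    idf = compute_idf_from_flat(flat)
    s = compute_s(idf, K)
    return LimitationState.full(idf, s, K, delta=delta)


def compute_idf_from_flat(flat):
    df = np.zeros(flat.V)
    for d in range(flat.D):
        for v in np.unique(flat.grp_word[flat.grp_day == d]):
            df[v] += 1
    return np.log(flat.D / df)


class TestGroupConditional:
    def test_singleton_group_reduces_to_token_conditional(self, small):
        flat, hp = small
        state = init_group_assignments(flat, hp, seed=0)[0]
        d, v = 0, int(flat.grp_word[0])
        w_grp = group_conditional(state, hp, d, v, A=1, support=np.arange(hp.K))
        w_tok = token_conditional(state, hp, d, v)
        assert np.allclose(w_grp, w_tok, rtol=1e-12)

    def test_empty_counts_pair_formula(self):
        # A=2, all counts zero, symmetric priors:
        # w_k = alpha(alpha+1) * beta(beta+1) / (V*beta (V*beta+1)), equal over k
        V, K, alpha, beta = 4, 3, 0.5, 0.2
        hp = Hyperparams.symmetric(K, V, alpha=alpha, beta=beta)
        state = CountState(ndk=np.zeros((1, K), int), nkv=np.zeros((K, V), int),
                           nk=np.zeros(K, int), nd=np.zeros(1, int),
                           z=np.zeros(0, int))
        w = group_conditional(state, hp, d=0, v=1, A=2, support=np.arange(K))
        expected = (alpha * (alpha + 1) * beta * (beta + 1)
                    / (V * beta * (V * beta + 1)))
        assert np.allclose(w, expected, rtol=1e-12)

    def test_empty_support_rejected(self, small):
        flat, hp = small
        state = init_group_assignments(flat, hp, seed=0)[0]
        with pytest.raises(ValueError):
            group_conditional(state, hp, 0, 0, 1, support=[])

    def test_matches_constrained_enumeration_oracle(self):
        """Gamma-ratio conditional equals the urn-derived constrained joint
        conditional on >=100 random tiny instances."""
        rng = np.random.default_rng(77)
        for _ in range(120):
            flat, hp = random_tiny_flat(rng, max_groups=4, max_k=3)
            zg = rng.integers(0, hp.K, flat.n_groups)
            g = int(rng.integers(0, flat.n_groups))
            state = CountState.from_assignments(
                flat, np.repeat(zg, flat.grp_mult), hp.K)
            d, v, A = flat.grp_day[g], flat.grp_word[g], flat.grp_mult[g]
            k_old = zg[g]
            state.ndk[d, k_old] -= A
            state.nkv[k_old, v] -= A
            state.nk[k_old] -= A
            state.nd[d] -= A
            w = group_conditional(state, hp, d, v, A, np.arange(hp.K))
            assert np.allclose(w / w.sum(),
                               group_conditional_oracle(flat, zg, g, hp.K, hp),
                               atol=1e-10)


class TestIdf:
    def test_ubiquitous_activity_has_zero_idf(self):
        corpus, vocab = build_corpus(
            [BillingRecord("T", "A", 1, d) for d in range(4)]
            + [BillingRecord("T", "B", 1, 0)])
        idf = compute_idf(corpus)
        assert idf[vocab.index("A")] == 0.0

    def test_rare_activity_has_log_d(self):
        corpus, vocab = build_corpus(
            [BillingRecord("T", "A", 1, d) for d in range(4)]
            + [BillingRecord("T", "B", 1, 0)])
        assert compute_idf(corpus)[vocab.index("B")] == pytest.approx(np.log(4))

    def test_hand_value(self):
        # 10 days, activity in 4 of them -> ln(2.5)
        records = [BillingRecord("T", "X", 1, d) for d in range(10)]
        records += [BillingRecord("T", "Y", 1, d) for d in range(4)]
        corpus, vocab = build_corpus(records)
        assert compute_idf(corpus)[vocab.index("Y")] == pytest.approx(
            0.9163, abs=1e-4)


class TestTopicNumberBound:
    def test_extreme_idf_maps_to_endpoints(self):
        s = compute_s(np.array([0.0, 2.0, 1.0]), K=5)
        assert s[0] == 5 and s[1] == 1

    def test_midpoint_rounds_half_up(self):
        # K=5, idf range [0,2], idf=1 -> 5 + 0.5*(1-5) = 3
        assert compute_s(np.array([0.0, 2.0, 1.0]), K=5)[2] == 3

    def test_constant_idf_degenerates_to_k(self):
        assert np.all(compute_s(np.full(4, 1.3), K=6) == 6)

    @pytest.mark.parametrize("mode", ["linear", "rank"])
    def test_monotone_non_increasing_in_idf(self, mode):
        idf = np.array([0.1, 0.5, 0.5, 1.7, 2.2, 3.0])
        s = compute_s(idf, K=4, mode=mode)
        assert np.all(np.diff(s) <= 0) and s.min() >= 1 and s.max() <= 4


class TestRelevantValue:
    def _state(self, nkv):
        nkv = np.asarray(nkv)
        return CountState(ndk=np.zeros((1, nkv.shape[0]), int), nkv=nkv,
                          nk=nkv.sum(1), nd=np.zeros(1, int), z=np.zeros(0, int))

    def test_rank_one_divides_by_one(self):
        nkv = np.array([[50, 10, 5]])
        phi = np.array([[0.7, 0.2, 0.1]])
        rv = compute_rv(self._state(nkv), TopicEstimates(phi=phi, theta=None))
        assert rv[0, 0] == 50.0

    def test_zero_count_gives_zero(self):
        nkv = np.array([[0, 10]])
        phi = np.array([[0.6, 0.4]])
        rv = compute_rv(self._state(nkv), TopicEstimates(phi=phi, theta=None))
        assert rv[0, 0] == 0.0

    def test_hand_value_rank_four(self):
        nkv = np.array([[1, 2, 3, 100, 4]])
        phi = np.array([[0.5, 0.2, 0.15, 0.1, 0.05]])  # activity 3 ranks 4th
        rv = compute_rv(self._state(nkv), TopicEstimates(phi=phi, theta=None))
        assert rv[0, 3] == 25.0

    def test_phi_ties_break_by_activity_index(self):
        nkv = np.array([[5, 5]])
        phi = np.array([[0.5, 0.5]])
        rv = compute_rv(self._state(nkv), TopicEstimates(phi=phi, theta=None))
        assert rv[0, 0] == 5.0 and rv[0, 1] == 2.5


class TestUpdateRelevantLists:
    def test_discards_minimum_rv_topic(self):
        # RV vector {50, 150, 5, 100, 60} with s=3: the third topic goes
        lim = LimitationState(idf=np.zeros(1), s=np.array([3]),
                              allowed=np.ones((5, 1), bool))
        rv = np.array([[50.0], [150.0], [5.0], [100.0], [60.0]])
        removed = update_relevant_lists(lim, rv)
        assert removed == [(0, 2)]
        assert list(lim.kappa(0)) == [0, 1, 3, 4]

    def test_list_at_target_size_is_frozen(self):
        lim = LimitationState(idf=np.zeros(1), s=np.array([2]),
                              allowed=np.array([[True], [True], [False]]))
        assert update_relevant_lists(lim, np.zeros((3, 1))) == []

    def test_rv_tie_removes_lowest_topic_index(self):
        lim = LimitationState(idf=np.zeros(1), s=np.array([2]),
                              allowed=np.ones((3, 1), bool))
        removed = update_relevant_lists(lim, np.array([[5.0], [5.0], [9.0]]))
        assert removed == [(0, 0)]

    def test_pruning_is_monotone_and_stops_at_s(self):
        rng = np.random.default_rng(3)
        K, V = 6, 5
        lim = LimitationState(idf=np.zeros(V), s=np.array([1, 2, 3, 6, 4]),
                              allowed=np.ones((K, V), bool))
        sizes = [lim.sizes.copy()]
        for _ in range(10):
            update_relevant_lists(lim, rng.random((K, V)))
            assert np.all(lim.sizes <= sizes[-1])       # never grows
            assert np.all(lim.sizes >= lim.s) or np.all(lim.sizes >= 1)
            sizes.append(lim.sizes.copy())
        assert np.array_equal(lim.sizes, lim.s)          # reaches target exactly


class TestAdjustedPhi:
    def test_zero_idf_zeroes_activity_in_every_topic(self):
        phi = np.array([[0.5, 0.5], [0.9, 0.1]])
        adj = adjusted_phi(TopicEstimates(phi=phi, theta=None),
                           np.array([0.0, 1.0]))
        assert np.all(adj.phi_bar[:, 0] == 0.0)

    def test_uniform_idf_preserves_rankings(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(6), size=3)
        adj = adjusted_phi(TopicEstimates(phi=phi, theta=None), np.full(6, 1.7))
        assert np.array_equal(adj.order_phi, adj.order_phi_bar)

    def test_hand_value(self):
        adj = adjusted_phi(TopicEstimates(phi=np.array([[0.2]]), theta=None),
                           np.array([0.9163]))
        assert adj.phi_bar[0, 0] == pytest.approx(0.18326, abs=1e-6)


class TestConstrainedSweep:
    def test_no_group_ever_has_mixed_topics(self, small):
        flat, hp = small
        lim = _full_limitation(flat, hp.K)
        state, zg = init_group_assignments(flat, hp, seed=1)
        rng = np.random.default_rng(1)
        for _ in range(5):
            constrained_sweep(state, hp, flat, lim, zg, rng)
            state.check()
            expanded = np.repeat(zg, flat.grp_mult)
            assert np.array_equal(state.z, expanded)

    def test_fixed_seed_replays_exactly(self, small):
        flat, hp = small
        outs = []
        for _ in range(2):
            lim = _full_limitation(flat, hp.K)
            state, zg = init_group_assignments(flat, hp, seed=2)
            rng = np.random.default_rng(2)
            for _ in range(4):
                constrained_sweep(state, hp, flat, lim, zg, rng)
            outs.append(zg.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_restricted_support_is_respected(self, small):
        flat, hp = small
        lim = _full_limitation(flat, hp.K)
        lim.allowed[0, :] = False    # globally forbid topic 0
        lim.allowed[1:, :] = True
        state, zg = init_group_assignments(flat, hp, seed=3)
        rng = np.random.default_rng(3)
        constrained_sweep(state, hp, flat, lim, zg, rng)
        assert np.all(zg != 0)


class TestRunCdg:
    def test_pruning_completes_and_history_is_consistent(self, small_synth):
        corpus = small_synth.corpus
        hp = Hyperparams.symmetric(4, corpus.V)
        res = run_cdg(corpus, hp, seed=5, total_sweeps=120, delta=20, burn_in=40)
        lim = res.limitation
        assert np.array_equal(lim.sizes, lim.s)
        removals_per_v = np.zeros(corpus.V, int)
        for _, v, _k in lim.history:
            removals_per_v[v] += 1
        assert np.array_equal(removals_per_v, hp.K - lim.sizes)

    def test_final_group_topics_lie_in_relevant_lists(self, small_synth):
        corpus = small_synth.corpus
        hp = Hyperparams.symmetric(4, corpus.V)
        res = run_cdg(corpus, hp, seed=6, total_sweeps=120, delta=20, burn_in=40)
        flat = FlatCorpus(corpus)
        for g in range(flat.n_groups):
            assert res.limitation.allowed[res.zg[g], flat.grp_word[g]]

    def test_warns_when_sweeps_cannot_finish_pruning(self, small_synth):
        corpus = small_synth.corpus
        hp = Hyperparams.symmetric(4, corpus.V)
        with pytest.warns(UserWarning, match="pruning"):
            run_cdg(corpus, hp, seed=0, total_sweeps=30, delta=20, burn_in=20)

    def test_runtime_scales_roughly_linearly_in_group_count(self):
        """Doubling the corpus should not blow past a linear trend."""
        import time
        import warnings

        from cdglda import synthetic

        hp_k = 4
        times = []
        for n_traces in (20, 40):
            synth = synthetic.generate(synthetic.GeneratorConfig(
                n_traces=n_traces, days_range=(8, 8), seed=11))
            hp = Hyperparams.symmetric(hp_k, synth.corpus.V)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # too few sweeps to prune: fine
                run_cdg(synth.corpus, hp, seed=1, total_sweeps=5,
                        delta=10, burn_in=20)  # warm compile + cache
            t0 = time.perf_counter()
            run_cdg(synth.corpus, hp, seed=1, total_sweeps=150,
                    delta=30, burn_in=30)
            times.append(time.perf_counter() - t0)
        assert times[1] < 6 * times[0]
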